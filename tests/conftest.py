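import numpy as np
import pytest

from ptmnet.ptm_dataset import PTMDataset, Protein, PTMSite, flank13
from ptmnet.synthetic import SyntheticConfig, simulate


def make_protein(protein_id: str, sequence: str, sites=(), gene_id: str | None = None) -> Protein:
    """Protein with sequence-consistent site records from (position, ptm_type) pairs."""
    p = Protein(protein_id, gene_id or protein_id, sequence)
    for position, ptm_type in sites:
        residue = sequence[position - 1]
        p.sites.append(PTMSite(p.protein_id, p.gene_id, position, residue, ptm_type, flank13(sequence, position)))
    p.sites.sort()
    return p


def make_dataset(*proteins: Protein) -> PTMDataset:
    ds = PTMDataset()
    for p in proteins:
        ds.proteins[p.protein_id] = p
    return ds


def write_fasta(path, proteins: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n{seq}\n")


def write_sites(path, rows) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgene_id\tposition\tresidue\tptm_type\tflank13\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


@pytest.fixture(scope="session")
def bundle():
    """Moderate synthetic bundle with hotspots and enriched complexes, shared read-only."""
    return simulate(SyntheticConfig(n_proteins=120, n_complexes=40, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
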