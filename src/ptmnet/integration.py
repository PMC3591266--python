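"""Where does complex-level enrichment live? Multiplicity-resolved resampling Z-scores.

Subunits of a group of enriched complexes are partitioned by PTM multiplicity
(the number of distinct modification types a protein carries, 1-4) and the
total record count per modification type is summed within each stratum,
giving a 4x4 observed signal matrix. The same matrix is computed for S random
draws of equally many complexes from the whole complex universe; the standard
Z-score of each observed cell against its resampling distribution localises
the enrichment to singly- or multiply-modified subunits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .complex_dataset import ProteinComplex
from .ptm_dataset import PTM_TYPES, PTMDataset

#: Z magnitudes above this are flagged as beyond the display scale.
Z_EXTREME = 35.0


@dataclass
class SignalMatrix:
    """Observed 4x4 totals with resampling null moments and Z-scores.

    Rows are PTM multiplicity 1-4, columns follow :data:`ptmnet.ptm_dataset.PTM_TYPES`.
    Cells whose null sd is zero have undefined Z (NaN) and are flagged in
    ``undefined`` rather than reported as infinite.
    """

    label: str
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    undefined: np.ndarray  # bool: null sd == 0
    extreme: np.ndarray  # bool: |Z| > Z_EXTREME
    S: int
    seed: int | None

    def to_frame(self, which: str = "z") -> pd.DataFrame:
        data = getattr(self, {"z": "z", "observed": "observed", "mean": "null_mean", "sd": "null_sd"}[which])
        return pd.DataFrame(data, index=[f"{m}_PTM" for m in range(1, 5)], columns=list(PTM_TYPES))


def partition_by_multiplicity(group: list[ProteinComplex], dataset: PTMDataset) -> dict[int, set[str]]:
    """Deduplicated union of member proteins split by distinct-type count 1-4.

    Unmodified members and members without a sequence are excluded.
    """
    proteins = set()
    for cx in group:
        proteins.update(m for m in cx.members if m in dataset)
    parts: dict[int, set[str]] = {m: set() for m in range(1, 5)}
    for pid in proteins:
        m = dataset[pid].multiplicity
        if m > 0:
            parts[m].add(pid)
    return parts


def observed_signal_matrix(group: list[ProteinComplex], dataset: PTMDataset) -> np.ndarray:
    """4x4 totals: cell (m, t) sums type-t records over multiplicity-m member proteins."""
    parts = partition_by_multiplicity(group, dataset)
    matrix = np.zeros((4, len(PTM_TYPES)), dtype=np.int64)
    for m, pids in parts.items():
        for pid in pids:
            counts = dataset[pid].counts_by_type()
            for t_i, t in enumerate(PTM_TYPES):
                matrix[m - 1, t_i] += counts[t]
    return matrix


def null_signal_distribution(
    n_complexes: int,
    all_complexes: list[ProteinComplex],
    dataset: PTMDataset,
    S: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """S signal matrices from uniform samples of n_complexes complexes without replacement."""
    if n_complexes > len(all_complexes):
        raise ValueError(f"cannot sample {n_complexes} from {len(all_complexes)} complexes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ordered = sorted(all_complexes, key=lambda c: c.complex_id)
    draws = np.empty((S, 4, len(PTM_TYPES)), dtype=np.int64)
    for s in range(S):
        idx = rng.choice(len(ordered), size=n_complexes, replace=False)
        draws[s] = observed_signal_matrix([ordered[i] for i in idx], dataset)
    return draws


def signal_zscores(
    observed: np.ndarray, null_draws: np.ndarray, label: str = "", seed: int | None = None
) -> SignalMatrix:
    """Standard Z-score per cell against the resampling distribution.

    The null sd uses the population (n-denominator) convention over the S
    draws. Cells with zero null spread get NaN Z and an ``undefined`` flag.
    """
    mean = null_draws.mean(axis=0)
    sd = null_draws.std(axis=0)  # ddof=0
    undefined = sd == 0
    z = np.full_like(mean, np.nan)
    np.divide(observed - mean, sd, out=z, where=~undefined)
    extreme = np.zeros_like(undefined)
    extreme[~undefined] = np.abs(z[~undefined]) > Z_EXTREME
    return SignalMatrix(label, observed, mean, sd, z, undefined, extreme, S=null_draws.shape[0], seed=seed)


def group_signal_matrix(
    group: list[ProteinComplex],
    all_complexes: list[ProteinComplex],
    dataset: PTMDataset,
    S: int = 1000,
    seed: int = 0,
    label: str = "",
) -> SignalMatrix:
    """Convenience: observed matrix, resampling null and Z-scores for one group."""
    observed = observed_signal_matrix(group, dataset)
    null = null_signal_distribution(len(group), all_complexes, dataset, S=S, seed=seed)
    return signal_zscores(observed, null, label=label, seed=seed)


def composition_shares(group: list[ProteinComplex], dataset: PTMDataset) -> dict[str, float]:
    """Percentage of total modification records per type over a complex group.

    Raises ValueError for a group with no modifications at all.
    """
    totals = {t: 0 for t in PTM_TYPES}
    proteins = set()
    for cx in group:
        proteins.update(m for m in cx.members if m in dataset)
    for pid in proteins:
        for t, c in dataset[pid].counts_by_type().items():
            totals[t] += c
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("group carries no modifications; shares undefined")
    return {t: 100.0 * totals[t] / grand for t in PTM_TYPES}
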