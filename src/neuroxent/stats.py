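"""Nonparametric connection screening and (metric, m, r) grid selection.

Each unordered channel pair in each band is one "connection".  Groups are
compared per connection with a Kruskal–Wallis test (three groups) or a
Mann–Whitney U test (two groups), and p-values are corrected with the
Benjamini–Hochberg step-up procedure.  The correction family is, by default,
the 171 connections of one band (``fdr_scope="band"``); pooling across bands
is available as ``fdr_scope="global"``.

Grid selection counts significant connections summed over the six bands for
every (metric, m, r) cell on the training set and picks the argmax; ties are
broken toward Cross-SampEn, then smaller m, then larger r.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .coupling import CouplingMatrix, GridKey, grid_subject_coupling, symmetrize_directed
from .preprocessing import BAND_ORDER, EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "kruskal_wallis",
    "mann_whitney_u",
    "bh_fdr",
    "screen_connections",
    "significant_counts",
    "parameter_grid_search",
    "GridSelectionResult",
]

METRIC_PREFERENCE = ("cross_sampen", "cross_apen")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (midranks, tie-corrected) and chi-square p-value.

    All values identical across all groups gives (H, p) = (0, 1) by
    convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    total_n = sum(a.size for a in arrays)
    if total_n < 5:
        warnings.warn("total n < 5: chi-square approximation unreliable", UserWarning)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (midranks; exact for small tie-free samples)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.all(np.concatenate([a, b]) == a[0]):
        return a.size * b.size / 2.0, 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p-values, reject flags).

    Adjusted p-values are the step-up minima capped at 1, returned in the
    original order; reject iff adjusted <= alpha.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    # multipletests rejects at adjusted <= alpha for fdr_bh; keep explicit
    return adjusted, adjusted <= alpha


SubjectMatrices = Mapping[str, Sequence[Mapping[str, CouplingMatrix]]]
"""group -> list of subjects -> band -> subject-level CouplingMatrix"""


def _prepare(matrix: CouplingMatrix) -> CouplingMatrix:
    return matrix if matrix.symmetric else symmetrize_directed(matrix)


def screen_connections(
    subject_matrices: SubjectMatrices,
    alpha: float = 0.05,
    test: str = "kruskal_3group",
    fdr_scope: str = "band",
) -> pd.DataFrame:
    """Per-connection group tests with BH-FDR correction.

    Parameters
    ----------
    subject_matrices
        ``{group: [ {band: CouplingMatrix}, ... ]}`` with one entry per
        subject (subject-level, epoch-averaged matrices).
    test : {"kruskal_3group", "mannwhitney_2group"}
    fdr_scope : {"band", "global"}
        Correction family: within each band, or pooled over all bands.

    Returns
    -------
    DataFrame with columns band, chan_i, chan_j, stat, p_raw, p_adj,
    significant (diagonal excluded).
    """
    if fdr_scope not in ("band", "global"):
        raise ValueError("fdr_scope must be 'band' or 'global'")
    groups = list(subject_matrices)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if test == "kruskal_3group":
        stat_fn = kruskal_wallis
    elif test == "mannwhitney_2group":
        if len(groups) != 2:
            raise ValueError("mannwhitney_2group requires exactly two groups")
        stat_fn = lambda gs: mann_whitney_u(gs[0], gs[1])  # noqa: E731
    else:
        raise ValueError(f"unknown test {test!r}")
    for g, subjects in subject_matrices.items():
        if len(subjects) < 2:
            raise ValueError(f"group {g!r} has fewer than two subjects")

    first = next(iter(subject_matrices[groups[0]]))
    bands = [b for b in BAND_ORDER if b in first] + [b for b in first if b not in BAND_ORDER]
    channels = first[bands[0]].channels
    for subjects in subject_matrices.values():
        for subj in subjects:
            for b in bands:
                if subj[b].channels != channels:
                    raise ValueError("mismatched channel sets across subjects")

    prepared = {
        g: [{b: _prepare(subj[b]) for b in bands} for subj in subjects]
        for g, subjects in subject_matrices.items()
    }
    rows = []
    for band in bands:
        for i, j in itertools.combinations(range(len(channels)), 2):
            per_group = [
                np.array([subj[band].values[i, j] for subj in prepared[g]])
                for g in groups
            ]
            pooled = np.concatenate(per_group)
            if np.all(pooled == pooled[0]):
                stat, p = 0.0, 1.0  # zero-variance connection: no evidence
            else:
                stat, p = stat_fn(per_group)
            rows.append((band, channels[i], channels[j], stat, p))
    table = pd.DataFrame(rows, columns=["band", "chan_i", "chan_j", "stat", "p_raw"])
    table["p_adj"] = np.nan
    table["significant"] = False
    if fdr_scope == "band":
        for band in bands:
            mask = table["band"] == band
            adj, rej = bh_fdr(table.loc[mask, "p_raw"].to_numpy(), alpha)
            table.loc[mask, "p_adj"] = adj
            table.loc[mask, "significant"] = rej
    else:
        adj, rej = bh_fdr(table["p_raw"].to_numpy(), alpha)
        table["p_adj"] = adj
        table["significant"] = rej
    table.attrs["alpha"] = alpha
    table.attrs["test"] = test
    table.attrs["fdr_scope"] = fdr_scope
    return table


def significant_counts(table: pd.DataFrame) -> pd.Series:
    """Significant-connection count per band (plus a 'total' entry)."""
    counts = table.groupby("band", sort=False)["significant"].sum().astype(int)
    counts.loc["total"] = int(table["significant"].sum())
    return counts


@dataclass
class GridSelectionResult:
    """Significant-connection counts per grid cell and the selected cell."""

    counts: pd.DataFrame  # index (metric, m, r); columns bands + total
    selected: GridKey
    discriminative: bool
    tables: dict[GridKey, pd.DataFrame]
    #: per-cell subject-level matrices, reusable downstream without recompute
    matrices: dict[GridKey, dict] | None = None

    @property
    def selected_metric(self) -> str:
        return self.selected[0]

    @property
    def selected_m(self) -> int:
        return self.selected[1]

    @property
    def selected_r(self) -> float:
        return self.selected[2]


def _tie_break_key(item: tuple[GridKey, int]) -> tuple:
    (metric, m, r), count = item
    return (-count, METRIC_PREFERENCE.index(metric), m, -r)


def parameter_grid_search(
    cohort: Mapping[str, Sequence[Mapping[str, EpochSet]]],
    metrics: Sequence[str] = ("cross_apen", "cross_sampen"),
    ms: Sequence[int] = (1, 2),
    rs: Sequence[float] = (0.10, 0.15, 0.20, 0.25),
    alpha: float = 0.05,
    fdr_scope: str = "band",
    **entropy_kwargs,
) -> GridSelectionResult:
    """Count significant connections for every (metric, m, r) cell and select.

    Parameters
    ----------
    cohort
        ``{group: [ {band: EpochSet}, ... ]}`` — per-group lists of subjects,
        each holding band-decomposed epochs (training set only).

    The per-subject coupling matrices for all cells are computed in one
    counting pass per channel pair and epoch.
    """
    if not metrics or not ms or not rs:
        raise ValueError("grid must be non-empty")
    for s in cohort.values():
        if any(split_violated := (es.split == "test") for subj in s for es in subj.values()):
            raise ValueError("parameter_grid_search must not see test-set epochs")
    cell_matrices: dict[GridKey, dict[str, list[dict[str, CouplingMatrix]]]] = {}
    for group, subjects in cohort.items():
        for subj_bands in subjects:
            per_band_grids = {
                band: grid_subject_coupling(
                    es, tuple(metrics), tuple(ms), tuple(rs), **entropy_kwargs
                )
                for band, es in subj_bands.items()
            }
            keys = next(iter(per_band_grids.values())).keys()
            for key in keys:
                cell = cell_matrices.setdefault(key, {})
                cell.setdefault(group, []).append(
                    {band: grids[key] for band, grids in per_band_grids.items()}
                )
    tables: dict[GridKey, pd.DataFrame] = {}
    count_rows = {}
    n_tests = None
    for key, subject_matrices in cell_matrices.items():
        table = screen_connections(subject_matrices, alpha, "kruskal_3group", fdr_scope)
        tables[key] = table
        counts = significant_counts(table)
        count_rows[key] = counts
        n_tests = len(table)
    counts_df = pd.DataFrame(count_rows).T.sort_index()
    counts_df.index.names = ["metric", "m", "r"]
    selected, best_count = min(
        ((key, int(count_rows[key]["total"])) for key in count_rows),
        key=_tie_break_key,
    )[0], max(int(c["total"]) for c in count_rows.values())
    discriminative = best_count > alpha * n_tests
    if not discriminative:
        logger.warning(
            "grid search: no discriminative cell (max count %d over %d tests)",
            best_count, n_tests,
        )
    logger.info("grid search selected %s (count=%d)", selected, best_count)
    return GridSelectionResult(
        counts=counts_df,
        selected=selected,
        discriminative=discriminative,
        tables=tables,
        matrices=cell_matrices,
    )
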