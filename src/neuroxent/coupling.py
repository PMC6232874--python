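"""Per-subject, per-band channel-coupling matrices.

For an M-channel epoch, entry (i, j) of the coupling matrix is the
cross-entropy between channels i and j.  Cross-SampEn matrices are symmetric
(upper triangle computed and mirrored); Cross-ApEn matrices are directed, and
``symmetrize_directed`` averages the two directions because the statistical
unit downstream is the unordered channel pair.  Subject-level matrices are the
arithmetic mean over that subject's artifact-free epochs.

``grid_epoch_matrices`` evaluates the full (metric, m, r) grid from a single
counting pass per channel pair; its entries are identical to per-cell
``epoch_coupling_matrix`` calls.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np

from ._kernels import cumulative_counts, grid_cell_values, match_counts
from .entropy import (
    DegenerateSeriesError,
    EntropyParams,
    apen_counts,
    apen_phi_difference,
    sampen_counts,
    sampen_value,
    znormalize,
)
from .preprocessing import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingMatrix",
    "FlatChannelError",
    "epoch_coupling_matrix",
    "average_matrices",
    "symmetrize_directed",
    "subject_coupling",
    "grid_epoch_matrices",
    "grid_subject_coupling",
    "n_pairs",
]

GridKey = tuple[str, int, float]


class FlatChannelError(DegenerateSeriesError):
    """An epoch contains a zero-variance channel."""


@dataclass
class CouplingMatrix:
    """M x M cross-entropy values over channels of one subject and band."""

    subject_id: str
    band: str | None
    params: EntropyParams
    channels: tuple[str, ...]
    values: np.ndarray
    n_epochs_averaged: int = 1
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        m = len(self.channels)
        if self.values.shape != (m, m):
            raise ValueError("values must be M x M with M = channel count")

    def pair_value(self, chan_a: str, chan_b: str) -> float:
        i, j = self.channels.index(chan_a), self.channels.index(chan_b)
        return float(self.values[i, j])


def n_pairs(n_channels: int) -> int:
    """Number of unordered channel pairs (171 for the 19-channel montage)."""
    return n_channels * (n_channels - 1) // 2


def _znorm_channels(epoch: np.ndarray) -> np.ndarray:
    out = np.empty_like(epoch, dtype=np.float64)
    for c in range(epoch.shape[0]):
        try:
            out[c] = znormalize(epoch[c])
        except DegenerateSeriesError as exc:
            raise FlatChannelError(f"flat channel {c} in epoch") from exc
    return out


def epoch_coupling_matrix(
    epoch: np.ndarray,
    params: EntropyParams,
    channels: tuple[str, ...] | None = None,
    subject_id: str = "",
    band: str | None = None,
    compute_diagonal: bool = True,
) -> CouplingMatrix:
    """Coupling matrix of one epoch (channels x samples).

    Raises
    ------
    FlatChannelError
        If any channel has zero variance in this epoch; callers averaging over
        epochs catch this and skip the epoch rather than zero-filling.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    m_ch = epoch.shape[0]
    if channels is None:
        channels = tuple(f"ch{i:02d}" for i in range(m_ch))
    if epoch.shape[1] < params.m + 2:
        raise ValueError("epoch too short for requested run length m")
    grid = grid_epoch_matrices(
        epoch,
        metrics=(params.metric,),
        ms=(params.m,),
        rs=(params.r,),
        channels=channels,
        subject_id=subject_id,
        band=band,
        compute_diagonal=compute_diagonal,
        variant=params.variant,
        self_match_exclusion=params.self_match_exclusion,
        on_no_matches=params.on_no_matches,
        correction=params.correction,
    )
    return grid[(params.metric, params.m, params.r)]


def grid_epoch_matrices(
    epoch: np.ndarray,
    metrics: tuple[str, ...],
    ms: tuple[int, ...],
    rs: tuple[float, ...],
    channels: tuple[str, ...] | None = None,
    subject_id: str = "",
    band: str | None = None,
    compute_diagonal: bool = True,
    variant: str = "canonical",
    self_match_exclusion: bool = False,
    on_no_matches: str = "surrogate",
    correction: str = "bias_max",
) -> dict[GridKey, CouplingMatrix]:
    """Coupling matrices of one epoch for every (metric, m, r) grid cell.

    A single counting pass per channel pair serves all cells, so the cost is
    nearly independent of the grid size.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    m_ch, n = epoch.shape
    if channels is None:
        channels = tuple(f"ch{i:02d}" for i in range(m_ch))
    ms = tuple(sorted(set(int(m) for m in ms)))
    rs_sorted = np.array(sorted(set(float(r) for r in rs)), dtype=np.float64)
    l_max = max(ms) + 1
    if n < max(ms) + 2:
        raise ValueError("epoch too short for requested run length m")
    norm = _znorm_channels(epoch)

    def _params(metric: str, m: int, r: float) -> EntropyParams:
        return EntropyParams(
            metric=metric, m=m, r=r,
            correction=correction, variant=variant,
            self_match_exclusion=self_match_exclusion, on_no_matches=on_no_matches,
        )

    cells: dict[GridKey, np.ndarray] = {
        (metric, m, float(r)): np.zeros((m_ch, m_ch))
        for metric in metrics for m in ms for r in rs_sorted
    }
    pair_iter = itertools.combinations(range(m_ch), 2)
    if compute_diagonal:
        pair_iter = itertools.chain(pair_iter, ((i, i) for i in range(m_ch)))
    # Default settings (canonical Cross-SampEn, bias-max Cross-ApEn) take a
    # jitted per-pair path covering all cells at once; it is numerically
    # equivalent to sampen_value / apen_phi_difference (same integer totals,
    # same per-template corrections).  Audit variants use the reference
    # functions cell by cell.
    want_sampen = "cross_sampen" in metrics
    want_apen = "cross_apen" in metrics
    fastpath = (not want_sampen or variant == "canonical") and (
        not want_apen or correction == "bias_max"
    )
    ms_arr = np.array(ms, dtype=np.int64)
    degenerate_total = np.zeros(2, dtype=np.int64)
    for i, j in pair_iter:
        full_h, full_t_h, last_h, diag_h = match_counts(norm[i], norm[j], l_max, rs_sorted)
        full = cumulative_counts(full_h)
        full_t = cumulative_counts(full_t_h)
        last = cumulative_counts(last_h)
        diag = cumulative_counts(diag_h)
        if fastpath:
            sampen_vals, apen_ij, apen_ji, degenerate = grid_cell_values(
                full, full_t, last, diag, ms_arr, n,
                want_sampen, want_apen, self_match_exclusion,
                on_no_matches == "inf",
            )
            degenerate_total += degenerate
            for mi, m in enumerate(ms):
                for ri, r in enumerate(rs_sorted):
                    r = float(r)
                    if want_sampen:
                        cells[("cross_sampen", m, r)][i, j] = sampen_vals[mi, ri]
                        cells[("cross_sampen", m, r)][j, i] = sampen_vals[mi, ri]
                    if want_apen:
                        # (i, j): ApEn(ch_j ‖ ch_i), reference templates from i
                        cells[("cross_apen", m, r)][i, j] = apen_ij[mi, ri]
                        cells[("cross_apen", m, r)][j, i] = apen_ji[mi, ri]
            continue
        for m in ms:
            for ri, r in enumerate(rs_sorted):
                r = float(r)
                if want_sampen:
                    counts = sampen_counts(
                        full[:, ri, :], last[:, ri, :], diag[:, ri, :],
                        m, n, self_match_exclusion,
                    )
                    val = sampen_value(counts, variant=variant, on_no_matches=on_no_matches)
                    cells[("cross_sampen", m, r)][i, j] = val
                    cells[("cross_sampen", m, r)][j, i] = val
                if want_apen:
                    # (i, j) entry: ApEn(ch_j ‖ ch_i), reference templates from i
                    c_ij = apen_counts(full[:, ri, :], m, n)
                    cells[("cross_apen", m, r)][i, j] = apen_phi_difference(c_ij, correction)
                    # transpose-direction counts from the same pass
                    c_ji = apen_counts(full_t[:, ri, :], m, n)
                    cells[("cross_apen", m, r)][j, i] = apen_phi_difference(c_ji, correction)
    if degenerate_total[0] or degenerate_total[1]:
        logger.warning(
            "Cross-SampEn degenerate cells: %d with no length-m matches "
            "(resolution bound), %d with no length-(m+1) matches (surrogate)",
            int(degenerate_total[0]), int(degenerate_total[1]),
        )
    return {
        key: CouplingMatrix(
            subject_id=subject_id,
            band=band,
            params=_params(*key),
            channels=channels,
            values=vals,
            n_epochs_averaged=1,
            symmetric=(key[0] == "cross_sampen"),
        )
        for key, vals in cells.items()
    }


def average_matrices(matrices: list[CouplingMatrix]) -> CouplingMatrix:
    """Elementwise mean of coupling matrices from the same subject/band/params."""
    if not matrices:
        raise ValueError("cannot average an empty list of matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if m.params != first.params or m.band != first.band or m.channels != first.channels:
            raise ValueError("matrices differ in params, band, or channels")
        if m.values.shape != first.values.shape:
            raise ValueError("matrices differ in shape")
    mean = np.mean([m.values for m in matrices], axis=0)
    return replace(first, values=mean, n_epochs_averaged=len(matrices))


def symmetrize_directed(matrix: CouplingMatrix) -> CouplingMatrix:
    """Average the two directions of a directed (Cross-ApEn) matrix."""
    if matrix.symmetric:
        logger.info("symmetrize_directed: matrix already symmetric; no-op")
        return replace(matrix)
    sym = 0.5 * (matrix.values + matrix.values.T)
    return replace(matrix, values=sym, symmetric=True)


def subject_coupling(
    epoch_set: EpochSet,
    params: EntropyParams,
    compute_diagonal: bool = True,
) -> CouplingMatrix:
    """Subject-level matrix: mean over epochs, skipping flat-channel epochs."""
    grids = grid_subject_coupling(
        epoch_set, metrics=(params.metric,), ms=(params.m,), rs=(params.r,),
        compute_diagonal=compute_diagonal,
        variant=params.variant, self_match_exclusion=params.self_match_exclusion,
        on_no_matches=params.on_no_matches, correction=params.correction,
    )
    return grids[(params.metric, params.m, params.r)]


def grid_subject_coupling(
    epoch_set: EpochSet,
    metrics: tuple[str, ...],
    ms: tuple[int, ...],
    rs: tuple[float, ...],
    compute_diagonal: bool = False,
    variant: str = "canonical",
    self_match_exclusion: bool = False,
    on_no_matches: str = "surrogate",
    correction: str = "bias_max",
) -> dict[GridKey, CouplingMatrix]:
    """Subject-level matrices for every grid cell (epoch mean per cell)."""
    per_cell: dict[GridKey, list[CouplingMatrix]] = {}
    skipped = 0
    for k, epoch in enumerate(epoch_set.epochs):
        try:
            grid = grid_epoch_matrices(
                epoch, metrics, ms, rs,
                channels=epoch_set.channels,
                subject_id=epoch_set.subject_id,
                band=epoch_set.band,
                compute_diagonal=compute_diagonal,
                variant=variant, self_match_exclusion=self_match_exclusion,
                on_no_matches=on_no_matches, correction=correction,
            )
        except FlatChannelError:
            skipped += 1
            logger.warning(
                "subject %s band %s: epoch %d skipped (flat channel)",
                epoch_set.subject_id, epoch_set.band, k,
            )
            continue
        for key, mat in grid.items():
            per_cell.setdefault(key, []).append(mat)
    if not per_cell:
        raise FlatChannelError(
            f"subject {epoch_set.subject_id}: every epoch had a flat channel"
        )
    if skipped:
        logger.info("subject %s: %d epoch(s) skipped", epoch_set.subject_id, skipped)
    return {key: average_matrices(mats) for key, mats in per_cell.items()}
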