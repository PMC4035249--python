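"""Window scoring against experimental per-residue profiles.

The core cross-validation step: each consecutive trajectory window yields a
computed per-residue profile (S² or local flexibility); every window is
scored by its Pearson correlation with the experimental profile over the
jointly valid residues, and windows are ranked. Selection criteria:

* ``max_r2``      — highest r² (used for S² vs experimental S²),
* ``max_abs_r``   — highest |r|,
* ``max_anticorr``— most negative r (local flexibility vs heteronuclear NOE
  are anticorrelated: mobile residues have high p and low NOE).

Ranking is deterministic; ties are broken by the earlier frame range. A
consensus ranking across observables orders windows by mean rank — agreement
of the S²-based and flexibility-based selections on the same window is the
evidence that the window represents the experimentally probed ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trajectory_io import ResidueProfile


class CorrelationError(ValueError):
    """Profiles cannot be correlated (too few shared residues, no variance)."""


@dataclass
class WindowResult:
    """One trajectory window's agreement with an experimental profile."""

    frame_range: tuple[int, int]
    window_label: str
    pearson_r: float
    r_squared: float
    n_shared_residues: int
    computed_profile: ResidueProfile | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def restrict_residue_range(profile: ResidueProfile,
                           residue_range: tuple[int, int] | None
                           ) -> ResidueProfile:
    """Mask out residues outside ``[first, last]`` (inclusive, 1-based)."""
    if residue_range is None:
        return profile
    first, last = residue_range
    keep = (profile.residue_index >= first) & (profile.residue_index <= last)
    return ResidueProfile(profile.residue_index, profile.values,
                          profile.mask & keep, label=profile.label,
                          sigma=profile.sigma)


def correlate_profiles(computed: ResidueProfile, experimental: ResidueProfile,
                       residue_range: tuple[int, int] | None = None,
                       method: str = "pearson") -> tuple[float, float, int]:
    """Correlation between two profiles over their joint validity mask.

    Returns ``(r, r_squared, n_shared)``. Raises :class:`CorrelationError`
    for fewer than 3 shared residues or a zero-variance restricted series.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    computed = restrict_residue_range(computed, residue_range)
    experimental = restrict_residue_range(experimental, residue_range)
    if not np.array_equal(computed.residue_index, experimental.residue_index):
        raise CorrelationError("profiles cover different residue ranges")
    mask = computed.mask & experimental.mask
    n_shared = int(mask.sum())
    if n_shared < 3:
        raise CorrelationError(
            f"only {n_shared} jointly valid residues; need at least 3")
    x = computed.values[mask]
    y = experimental.values[mask]
    for name, series in (("computed", x), ("experimental", y)):
        if np.ptp(series) == 0:
            raise CorrelationError(f"{name} profile "
                                   f"({(computed if name == 'computed' else experimental).label!r}) "
                                   f"has zero variance over the shared residues")
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    else:
        r = float(stats.spearmanr(x, y).statistic)
    return r, r * r, n_shared


def _window_label(frame_range: tuple[int, int], frame_spacing: float | None
                  ) -> str:
    if frame_spacing is None:
        return f"frames {frame_range[0]}-{frame_range[1]}"
    t0 = frame_range[0] * frame_spacing / 1000.0  # ps -> ns
    t1 = frame_range[1] * frame_spacing / 1000.0
    return f"{t0:g}-{t1:g} ns"


def select_best_window(windows, experimental: ResidueProfile,
                       criterion: str = "max_r2",
                       residue_range: tuple[int, int] | None = None,
                       frame_spacing: float | None = None,
                       method: str = "pearson") -> list[WindowResult]:
    """Score every ``(frame_range, profile)`` window and rank them.

    Windows whose correlation fails (too few shared residues, flat profile)
    are ranked last with the error recorded, never dropped silently.
    """
    if criterion not in ("max_r2", "max_abs_r", "max_anticorr"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if not windows:
        raise ValueError("need at least one window")
    results = []
    for frame_range, profile in windows:
        label = _window_label(frame_range, frame_spacing)
        try:
            r, r2, n = correlate_profiles(profile, experimental,
                                          residue_range, method)
            results.append(WindowResult(tuple(frame_range), label, r, r2, n,
                                        computed_profile=profile))
        except CorrelationError as exc:
            results.append(WindowResult(tuple(frame_range), label,
                                        np.nan, np.nan, 0,
                                        computed_profile=profile,
                                        error=str(exc)))

    def score(res: WindowResult) -> float:
        if res.failed:
            return -np.inf
        if criterion == "max_r2":
            return res.r_squared
        if criterion == "max_abs_r":
            return abs(res.pearson_r)
        return -res.pearson_r  # max_anticorr: most negative r first

    results.sort(key=lambda res: (-score(res), res.frame_range))
    return results


def consensus_windows(rankings: list[list[WindowResult]]) -> list[WindowResult]:
    """Order windows by mean rank across several rankings.

    Ties are broken by the best single rank, then by frame range. All
    rankings must cover the same window set.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    key_sets = [frozenset(res.frame_range for res in rk) for rk in rankings]
    if len(set(key_sets)) != 1:
        raise ValueError("rankings cover different window sets")
    mean_rank: dict[tuple, list] = {}
    for rk in rankings:
        for pos, res in enumerate(rk, start=1):
            mean_rank.setdefault(res.frame_range, []).append(pos)
    rep = {res.frame_range: res for res in rankings[0]}
    order = sorted(mean_rank,
                   key=lambda fr: (np.mean(mean_rank[fr]),
                                   min(mean_rank[fr]), fr))
    return [rep[fr] for fr in order]
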