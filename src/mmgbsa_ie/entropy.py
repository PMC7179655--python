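"""Interaction entropy: −TΔS from interaction-energy fluctuations.

The entropic contribution is estimated directly from the exponential average
of interaction-energy fluctuations along the trajectory,

    −TΔS = kT·ln⟨exp(βΔE_int)⟩,  ΔE_int = E_int − ⟨E_int⟩,  β = 1/kT,

evaluated with a log-sum-exp guard. Jensen's inequality makes the estimate
non-negative, zero only for a constant series. A single-pass 3-standard-
deviation filter (mean/SD of the unfiltered series) removes spikes before
the exponential average; iteration would change the estimator, so it is not
iterated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import BOLTZMANN_KCAL, DEFAULT_TEMPERATURE
from .errors import EmptyInputError, MMGBSAError, WindowError

__all__ = ["IEResult", "WindowPlan", "Window", "filter_outliers",
           "interaction_entropy", "plan_windows", "aggregate_windows"]


@dataclass
class IEResult:
    mean_e_int: float          # ⟨E_int⟩, kcal/mol
    minus_t_ds: float          # −TΔS ≥ 0, kcal/mol
    n_frames_used: int
    n_frames_filtered: int
    temperature: float


@dataclass
class Window:
    replicate: int
    start_frame: int
    stop_frame: int            # exclusive

    @property
    def n_frames(self) -> int:
        return self.stop_frame - self.start_frame


@dataclass
class WindowPlan:
    """Window/frame protocol for free-energy averaging.

    Defaults follow the production protocol: five non-overlapping 5-ns
    windows per 100-ns replicate, three replicates (15 windows total),
    enthalpy from 100 equally spaced frames per window, entropy from every
    frame in the window.
    """

    window_length_ps: float = 5000.0
    n_windows_per_replicate: int = 5
    n_replicates: int = 3
    enthalpy_frames_per_window: int = 100
    explicit_windows: list[Window] | None = None


def filter_outliers(series: np.ndarray, k_sd: float = 3.0) -> np.ndarray:
    """Single-pass outlier rejection.

    Keeps values within ``k_sd`` standard deviations of the mean, both
    computed once on the full input; order preserved.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise EmptyInputError("empty energy series")
    if series.size < 2:
        return series.copy()
    mean = series.mean()
    sd = series.std(ddof=1)
    if sd == 0.0:
        return series.copy()
    return series[np.abs(series - mean) <= k_sd * sd]


def interaction_entropy(series: np.ndarray, T: float = DEFAULT_TEMPERATURE,
                        k_sd: float | None = None) -> IEResult:
    """−TΔS (kcal/mol) from an interaction-energy series.

    ``k_sd`` optionally applies :func:`filter_outliers` first and records how
    many frames were dropped. Computed as kT·(logsumexp(βΔE) − ln N), which
    never overflows.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise EmptyInputError("empty energy series")
    if not np.all(np.isfinite(series)):
        raise MMGBSAError("non-finite interaction energies")
    n_in = series.size
    if k_sd is not None:
        series = filter_outliers(series, k_sd)
    kT = BOLTZMANN_KCAL * T
    mean = series.mean()
    fluct = (series - mean) / kT
    minus_t_ds = kT * (logsumexp(fluct) - np.log(series.size))
    return IEResult(
        mean_e_int=float(mean),
        minus_t_ds=max(0.0, float(minus_t_ds)),
        n_frames_used=int(series.size),
        n_frames_filtered=int(n_in - series.size),
        temperature=float(T),
    )


def _rolling_sd(x: np.ndarray, w: int) -> np.ndarray:
    """Sample SD of every length-w contiguous window, via prefix sums (O(N))."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    tot = s1[w:] - s1[:-w]
    tot2 = s2[w:] - s2[:-w]
    var = np.maximum(0.0, (tot2 - tot * tot / w) / (w - 1))
    return np.sqrt(var)


def plan_windows(traj_lengths_ps,
                 plan: WindowPlan | None = None,
                 stability_series=None,
                 frame_interval_ps: float = 1.0) -> list[Window]:
    """Choose the analysis windows for each replicate.

    Per replicate, greedily selects the ``n_windows_per_replicate``
    non-overlapping windows that minimise the standard deviation of the
    stability series (ligand RMSD to the crystal frame) inside the window;
    ties break toward the earliest start. A flat series therefore yields the
    earliest windows. ``plan.explicit_windows`` overrides selection.
    """
    plan = plan or WindowPlan()
    if plan.explicit_windows is not None:
        return list(plan.explicit_windows)
    lengths = list(np.atleast_1d(traj_lengths_ps).astype(float))
    if len(lengths) != plan.n_replicates:
        raise WindowError(
            f"plan expects {plan.n_replicates} replicates, got {len(lengths)}")
    w = int(round(plan.window_length_ps / frame_interval_ps))
    windows: list[Window] = []
    for rep, length in enumerate(lengths):
        n_frames = int(round(length / frame_interval_ps))
        if n_frames < plan.n_windows_per_replicate * w:
            raise WindowError(
                f"replicate {rep}: {length} ps too short for "
                f"{plan.n_windows_per_replicate} windows of {plan.window_length_ps} ps")
        if stability_series is None:
            series = np.zeros(n_frames)
        else:
            series = np.asarray(stability_series[rep], dtype=float)
            if len(series) != n_frames:
                raise WindowError(
                    f"replicate {rep}: stability series length {len(series)} "
                    f"!= {n_frames} frames")
        cost = _rolling_sd(series, w)
        chosen: list[int] = []
        blocked = np.zeros(len(cost), dtype=bool)
        for _ in range(plan.n_windows_per_replicate):
            masked = np.where(blocked, np.inf, cost)
            start = int(np.argmin(masked))  # earliest minimum on ties
            if not np.isfinite(masked[start]):
                chosen = None
                break
            chosen.append(start)
            lo = max(0, start - w + 1)
            blocked[lo:start + w] = True
        if chosen is None:
            # greedy painted itself into a corner (little slack); fall back
            # to the best equally phased partition
            slack = n_frames - plan.n_windows_per_replicate * w
            offsets = range(slack + 1)
            best = min(offsets, key=lambda o: cost[
                [o + j * w for j in range(plan.n_windows_per_replicate)]].sum())
            chosen = [best + j * w for j in range(plan.n_windows_per_replicate)]
        windows.extend(Window(rep, s, s + w) for s in chosen)
    windows.sort(key=lambda win: (win.replicate, win.start_frame))
    return windows


def aggregate_windows(values) -> tuple[float, float]:
    """Mean and sample SD (n−1 denominator) across window-level values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise WindowError("need at least 2 windows to aggregate")
    return float(values.mean()), float(values.std(ddof=1))
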