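"""Time-resolved information measures over stimulus-response recordings.

The circuit is deterministic, so probability distributions are induced by a
distribution over the stimulus: many trials are run, each with a stimulus
value drawn from a known ensemble, and at each time point the joint
distribution p_t(s, r) of (stimulus, response) is estimated from the trial
ensemble.  Estimation uses average shifted histograms (ASH): a histogram
grid of ``bins`` bins per dimension is shifted ``shifts`` times by fractions
of a bin width along each dimension and the resulting histograms (all
``shifts**d`` combinations) are averaged.

The averaging over shifts is computed in closed form: on the fine grid of
``bins * shifts`` cells per dimension, a sample whose fine index has residue
``r`` (mod ``shifts``) lands in coarse bin ``f // shifts`` for
``shifts - r`` of the shifted grids and in the next coarse bin for the
remaining ``r``, so the exact ASH weight of a sample is a product of
per-dimension linear weights (1 - r/shifts, r/shifts) on two adjacent
coarse bins.  The coarse grid therefore has ``bins + 1`` slots per
dimension with slot j effectively centred at ``lo + j * width``.

Measures: mutual information I(S;R), stimulus-specific information
I(S=s;R), and transfer entropy T(Y->X) = I(X_t; Y_{t-1} | X_{t-1}), all in
bits and, where meaningful, normalized by the stimulus entropy H(S) so that
0 means the stimulus is indistinguishable from the response and 1 means it
is uniquely determined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assays import Recording

__all__ = [
    "ash_joint",
    "estimate_joint",
    "TimeVaryingJoint",
    "InfoProfile",
    "entropy",
    "mutual_information",
    "specific_information",
    "conditional_mutual_information",
    "transfer_entropy",
    "mi_profile",
    "specific_info_profile",
    "te_profile",
    "time_resolved",
    "layer_preservation",
    "LAYERS",
]

#: default estimator settings for the study conditions
DEFAULT_BINS = 50
DEFAULT_SHIFTS = 12

#: layer -> observed variables, used by layer-level (joint-response) analyses
LAYERS = {
    "ASE": ("V_ON", "V_OFF"),
    "AIY": ("sigma_AIYL", "sigma_AIYR"),
    "AIZ": ("sigma_AIZL", "sigma_AIZR"),
    "SMB": ("sigma_SMBDL", "sigma_SMBDR", "sigma_SMBVL", "sigma_SMBVR"),
    "neck": ("phi",),
}


# ---------------------------------------------------------------------- #
# ASH density estimation
# ---------------------------------------------------------------------- #


def _fine_codes(x: np.ndarray, lo: float, hi: float, bins: int, shifts: int):
    """Coarse base index and upper-corner weight for every sample.

    Returns (base, w_up) where the ASH mass of a sample splits as
    (1 - w_up) on coarse slot ``base`` and ``w_up`` on slot ``base + 1``.
    Degenerate range (hi == lo, e.g. a constant response) puts all mass in
    slot 0.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("non-finite binning range")
    if hi <= lo:
        return np.zeros(x.shape, dtype=np.int64), np.zeros(x.shape)
    n_fine = bins * shifts
    fine = np.floor((x - lo) / (hi - lo) * n_fine).astype(np.int64)
    np.clip(fine, 0, n_fine - 1, out=fine)
    base, resid = np.divmod(fine, shifts)
    return base, resid / shifts


def ash_joint(
    cols: Sequence[np.ndarray],
    ranges: Sequence[tuple[float, float]],
    bins: Sequence[int] | int,
    shifts: Sequence[int] | int,
) -> np.ndarray:
    """Average-shifted-histogram joint density of d co-indexed samples.

    ``cols`` is a sequence of d equal-length 1-D arrays; ``ranges`` the
    (lo, hi) binning range per dimension.  Returns the probability array of
    shape ``tuple(b + 1 for b in bins)``; it sums to 1 and equals the
    average of all ``prod(shifts)`` shifted plain histograms.
    """
    d = len(cols)
    n = len(cols[0])
    if n < 1:
        raise ValueError("need at least one sample")
    bins = [bins] * d if np.isscalar(bins) else list(bins)
    shifts = [shifts] * d if np.isscalar(shifts) else list(shifts)
    for b, m in zip(bins, shifts):
        if b < 1 or m < 1:
            raise ValueError("bins and shifts must be >= 1")
    bases, ups = [], []
    for x, (lo, hi), b, m in zip(cols, ranges, bins, shifts):
        base, w_up = _fine_codes(x, lo, hi, b, m)
        bases.append(base)
        ups.append(w_up)
    shape = tuple(b + 1 for b in bins)
    out = np.zeros(int(np.prod(shape)))
    strides = np.cumprod([1] + list(shape[::-1]))[:-1][::-1]
    for corner in itertools.product((0, 1), repeat=d):
        code = np.zeros(n, dtype=np.int64)
        w = np.ones(n)
        for dim, up in enumerate(corner):
            code += (bases[dim] + up) * strides[dim]
            w = w * (ups[dim] if up else (1.0 - ups[dim]))
        out += np.bincount(code, weights=w, minlength=out.size)
    return (out / n).reshape(shape)


@dataclass
class TimeVaryingJoint:
    """Per-timestep joint distribution p_t(s, r) for one response variable."""

    p: np.ndarray  # (T, n_s_slots, n_r_slots...)
    s_range: tuple[float, float]
    r_ranges: list[tuple[float, float]]
    bins: list[int]
    shifts: list[int]
    t: np.ndarray = field(default=None)  # type: ignore[assignment]

    def stimulus_marginal(self, time_index: int = 0) -> np.ndarray:
        axes = tuple(range(1, self.p.ndim - 1 + 1))[0:]
        return self.p[time_index].sum(axis=tuple(range(1, self.p.ndim - 1)))


def _var_range(rec: Recording, name: str) -> tuple[float, float]:
    """Binning range for a response variable.

    Synaptic outputs are binned over their natural (0, 1) codomain — the
    grid resolution is absolute, so a cell whose output saturates (varies
    by less than a bin) genuinely carries no resolvable information, which
    is the mechanism behind information gating and the left/right
    asymmetries.  Other variables (sensor potentials, neck velocity) have
    no natural bounds and use their observed range.
    """
    if name.startswith("sigma_"):
        return 0.0, 1.0
    x = rec.trace(name)
    return float(x.min()), float(x.max())


def _stim_range(rec: Recording) -> tuple[float, float]:
    lo = rec.meta.get("stim_lo")
    hi = rec.meta.get("stim_hi")
    if lo is None or hi is None:
        return float(rec.stimulus.min()), float(rec.stimulus.max())
    return float(lo), float(hi)


def _check_stimulus(rec: Recording) -> None:
    s = rec.stimulus
    if s.size < 2:
        raise ValueError("need at least two trials")
    if np.ptp(s) == 0:
        raise ValueError("constant stimulus: H(S) = 0, normalization undefined")


def _joint_bins(n_vars: int, bins: int) -> int:
    """Per-dimension response bins for joint (multi-variable) responses.

    Reduced so the total number of response cells stays near ``bins**2``
    (sample-size sanity at the study's 2200 presentations).
    """
    if n_vars == 1:
        return bins
    return max(2, int(round(bins ** (2.0 / n_vars))))


def estimate_joint(
    rec: Recording,
    variable: str | Sequence[str],
    time_index: int | None = None,
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
    stim_bins: int | None = None,
) -> TimeVaryingJoint:
    """Estimate p_t(s, r) for one (possibly joint) response variable.

    ``variable`` may be a single observable name or a tuple of names (the
    response is then binned jointly with reduced per-dimension bins).  With
    ``time_index`` given, only that time point is estimated; otherwise the
    full time course.
    """
    _check_stimulus(rec)
    names = (variable,) if isinstance(variable, str) else tuple(variable)
    stim_bins = bins if stim_bins is None else stim_bins
    r_bins = _joint_bins(len(names), bins)
    s_range = _stim_range(rec)
    r_ranges = [_var_range(rec, v) for v in names]
    t_sel = range(rec.n_steps) if time_index is None else [time_index]
    all_bins = [stim_bins] + [r_bins] * len(names)
    all_shifts = [shifts] * (1 + len(names))
    ps = []
    for ti in t_sel:
        cols = [rec.stimulus] + [rec.trace(v)[:, ti] for v in names]
        ps.append(ash_joint(cols, [s_range] + r_ranges, all_bins, all_shifts))
    return TimeVaryingJoint(
        p=np.stack(ps),
        s_range=s_range,
        r_ranges=r_ranges,
        bins=all_bins,
        shifts=all_shifts,
        t=rec.t[list(t_sel)],
    )


# ---------------------------------------------------------------------- #
# discrete information measures (0 log 0 = 0 convention throughout)
# ---------------------------------------------------------------------- #


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    mask = p > 0
    out[mask] = p[mask] * np.log2(p[mask])
    return out


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits of a (possibly multi-dim) distribution."""
    return float(-_xlogx(np.asarray(p, dtype=float)).sum())


def mutual_information(joint: np.ndarray) -> float:
    """I(S;R) in bits from a joint p(s, r).

    The first axis is the stimulus; all remaining axes form the (possibly
    joint) response.
    """
    p = np.asarray(joint, dtype=float)
    if p.ndim > 2:
        p = p.reshape(p.shape[0], -1)
    ps = p.sum(axis=1)
    pr = p.sum(axis=0)
    return float(entropy(ps) + entropy(pr) - entropy(p))


def specific_information(joint: np.ndarray, s_index: int) -> float:
    """I(S = s_i; R) in bits: expected reduction in surprise about s_i.

    Defined as sum_j p(r_j | s_i) [log 1/p(s_i) - log 1/p(s_i | r_j)].
    Raises if p(s_i) = 0.  Averaging over p(s) recovers I(S;R).
    """
    p = np.asarray(joint, dtype=float)
    if p.ndim > 2:
        p = p.reshape(p.shape[0], -1)
    ps = p.sum(axis=1)
    if ps[s_index] <= 0:
        raise ValueError(f"p(s) = 0 for stimulus slot {s_index}")
    pr = p.sum(axis=0)
    row = p[s_index]
    mask = row > 0
    p_r_given_s = row[mask] / ps[s_index]
    p_s_given_r = row[mask] / pr[mask]
    return float(
        np.sum(p_r_given_s * (np.log2(p_s_given_r) - np.log2(ps[s_index])))
    )


def specific_information_all(joint: np.ndarray) -> np.ndarray:
    """Specific information for every stimulus slot (nan where p(s)=0)."""
    p = np.asarray(joint, dtype=float)
    if p.ndim > 2:
        p = p.reshape(p.shape[0], -1)
    ps = p.sum(axis=1)
    out = np.full(p.shape[0], np.nan)
    for i in np.nonzero(ps > 0)[0]:
        out[i] = specific_information(p, int(i))
    return out


def conditional_mutual_information(joint: np.ndarray) -> float:
    """I(X; Y | Z) in bits from a joint p(x, y, z).

    Computed as H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z).
    """
    p = np.asarray(joint, dtype=float)
    if p.ndim != 3:
        raise ValueError("expects a 3-D joint p(x, y, z)")
    h_xz = entropy(p.sum(axis=1))
    h_yz = entropy(p.sum(axis=0))
    h_z = entropy(p.sum(axis=(0, 1)))
    h_xyz = entropy(p)
    return float(h_xz + h_yz - h_z - h_xyz)


# ---------------------------------------------------------------------- #
# time-resolved profiles
# ---------------------------------------------------------------------- #


@dataclass
class InfoProfile:
    """A time course of one information measure for one target variable."""

    t: np.ndarray
    bits: np.ndarray
    H_S: float
    measure: str
    variables: tuple[str, ...]
    stimulus_feature: str = ""

    @property
    def normalized(self) -> np.ndarray:
        return self.bits / self.H_S

    def time_average(self, normalized: bool = True) -> float:
        vals = self.normalized if normalized else self.bits
        return float(np.mean(vals))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.t,
                "variable": "+".join(self.variables),
                "measure": self.measure,
                "bits": self.bits,
                "normalized": self.normalized,
            }
        )


def _stimulus_entropy(rec: Recording, bins: int, shifts: int) -> float:
    s_range = _stim_range(rec)
    ps = ash_joint([rec.stimulus], [s_range], [bins], [shifts])
    return entropy(ps)


def mi_profile(
    rec: Recording,
    variable: str | Sequence[str],
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
    stim_bins: int | None = None,
    time_chunk: int = 64,
) -> InfoProfile:
    """Time-resolved mutual information between the stimulus and a variable.

    Computed chunked over time to bound memory at high bin counts.
    """
    _check_stimulus(rec)
    names = (variable,) if isinstance(variable, str) else tuple(variable)
    stim_bins = bins if stim_bins is None else stim_bins
    r_bins = _joint_bins(len(names), bins)
    s_range = _stim_range(rec)
    r_ranges = [_var_range(rec, v) for v in names]
    all_bins = [stim_bins] + [r_bins] * len(names)
    all_shifts = [shifts] * (1 + len(names))
    traces = [rec.trace(v) for v in names]
    out = np.empty(rec.n_steps)
    for start in range(0, rec.n_steps, time_chunk):
        stop = min(start + time_chunk, rec.n_steps)
        for ti in range(start, stop):
            cols = [rec.stimulus] + [tr[:, ti] for tr in traces]
            p = ash_joint(cols, [s_range] + r_ranges, all_bins, all_shifts)
            out[ti] = mutual_information(p)
    h_s = _stimulus_entropy(rec, stim_bins, shifts)
    return InfoProfile(
        t=rec.t.copy(),
        bits=out,
        H_S=h_s,
        measure="MI",
        variables=names,
        stimulus_feature=rec.meta.get("feature", ""),
    )


def specific_info_profile(
    rec: Recording,
    variable: str | Sequence[str],
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
    stim_bins: int | None = None,
):
    """Specific information surface I(S = s; R(t)) over (time, stimulus slot).

    Returns (profile_surface with shape (T, n_s_slots), stimulus slot
    centres, H_S).  Entries are nan where the estimated p(s) is zero.
    """
    _check_stimulus(rec)
    names = (variable,) if isinstance(variable, str) else tuple(variable)
    stim_bins = bins if stim_bins is None else stim_bins
    r_bins = _joint_bins(len(names), bins)
    s_range = _stim_range(rec)
    r_ranges = [_var_range(rec, v) for v in names]
    all_bins = [stim_bins] + [r_bins] * len(names)
    all_shifts = [shifts] * (1 + len(names))
    traces = [rec.trace(v) for v in names]
    surface = np.empty((rec.n_steps, stim_bins + 1))
    for ti in range(rec.n_steps):
        cols = [rec.stimulus] + [tr[:, ti] for tr in traces]
        p = ash_joint(cols, [s_range] + r_ranges, all_bins, all_shifts)
        surface[ti] = specific_information_all(p)
    lo, hi = s_range
    width = (hi - lo) / stim_bins
    centres = lo + np.arange(stim_bins + 1) * width
    h_s = _stimulus_entropy(rec, stim_bins, shifts)
    return surface, centres, h_s


def transfer_entropy(
    rec: Recording,
    source: str,
    target: str,
    time_index: int,
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
) -> float:
    """Transfer entropy T(Y->X) = I(X_t; Y_{t-1} | X_{t-1}) at one time.

    Estimated from the trial ensemble with the same ASH binning as mutual
    information, applied per dimension of the (X_t, Y_{t-1}, X_{t-1})
    triple.  Lag-1 source state, order-1 conditioning on the target history
    (the deterministic-system convention).
    """
    if time_index < 1:
        raise ValueError("transfer entropy needs time_index >= 1")
    if rec.n_trials < 2:
        raise ValueError("need at least two trials")
    x = rec.trace(target)
    y = rec.trace(source)
    x_range = _var_range(rec, target)
    y_range = _var_range(rec, source)
    cols = [x[:, time_index], y[:, time_index - 1], x[:, time_index - 1]]
    p = ash_joint(
        cols, [x_range, y_range, x_range], [bins] * 3, [shifts] * 3
    )
    return conditional_mutual_information(p)


def te_profile(
    rec: Recording,
    source: str,
    target: str,
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
) -> InfoProfile:
    """Time-resolved transfer entropy from source to target (t >= 1)."""
    x = rec.trace(target)
    y = rec.trace(source)
    x_range = _var_range(rec, target)
    y_range = _var_range(rec, source)
    out = np.empty(rec.n_steps - 1)
    for ti in range(1, rec.n_steps):
        cols = [x[:, ti], y[:, ti - 1], x[:, ti - 1]]
        p = ash_joint(cols, [x_range, y_range, x_range], [bins] * 3, [shifts] * 3)
        out[ti - 1] = conditional_mutual_information(p)
    h_s = _stimulus_entropy(rec, bins, shifts)
    return InfoProfile(
        t=rec.t[1:].copy(),
        bits=out,
        H_S=h_s,
        measure="TE",
        variables=(source, target),
        stimulus_feature=rec.meta.get("feature", ""),
    )


def time_resolved(
    rec: Recording,
    measure: str,
    variables,
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
):
    """Dispatch a time-resolved measure request.

    ``measure`` is "MI", "specific" or "TE"; ``variables`` is a variable
    name (or tuple for joint responses), or a (source, target) pair for TE.
    """
    if measure == "MI":
        return mi_profile(rec, variables, bins=bins, shifts=shifts)
    if measure == "specific":
        return specific_info_profile(rec, variables, bins=bins, shifts=shifts)
    if measure == "TE":
        source, target = variables
        return te_profile(rec, source, target, bins=bins, shifts=shifts)
    raise ValueError(f"unknown measure {measure!r}")


def layer_preservation(
    rec: Recording,
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
) -> dict[str, InfoProfile]:
    """Normalized MI of the stimulus with each layer's joint response.

    Layers: ASE pair, AIY pair, AIZ pair, SMB quadruple (jointly binned) and
    the neck.  In an open-loop chain the downstream layers cannot exceed the
    upstream ones (data-processing inequality, up to estimator tolerance).
    """
    return {
        layer: mi_profile(rec, names, bins=bins, shifts=shifts)
        for layer, names in LAYERS.items()
    }
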