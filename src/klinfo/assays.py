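"""Open-loop stimulation assays.

The information analysis isolates the circuit from its environment: a
stimulus ensemble (many trials, each with a stimulus value drawn from a
known distribution) is applied in open loop and every observable is
recorded over a fixed window.  Two protocols are used:

* concentration step: the concentration jumps by a trial-specific amount
  delta-c at a configured onset time / locomotion phase;
* information clamp: the concentration ramps linearly at a trial-specific
  rate c-dot for the whole window, so the chemosensors hold a constant
  output and the only time dependence left downstream is the oscillatory
  pattern-generator drive.

Stimulus values default to the study conditions: 2200 presentations drawn
uniformly from +/-0.01 (concentration units for steps, concentration per
second for clamps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .circuit import DT, NO_LESION, OBSERVABLES, CircuitParams, LesionSet, simulate_open_loop

__all__ = [
    "StimulusEnsemble",
    "Recording",
    "concentration_step_assay",
    "information_clamp_assay",
    "phase_sweep",
    "BASELINE_CONCENTRATION",
    "N_TRIALS_DEFAULT",
    "N_TRIALS_FAST",
]

#: baseline concentration; arbitrary, since the sensory stage only responds
#: to changes (translation invariance is asserted by a test)
BASELINE_CONCENTRATION = 1.0

N_TRIALS_DEFAULT = 2200
N_TRIALS_FAST = 220


@dataclass
class StimulusEnsemble:
    """A set of stimulus values for one assay.

    ``feature`` is "dc" (step size) or "cdot" (clamp rate, per second);
    ``distribution`` tags how the values were drawn ("uniform" or
    "empirical").
    """

    feature: str
    values: np.ndarray
    distribution: str = "uniform"
    lo: float = -0.01
    hi: float = 0.01

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.feature not in ("dc", "cdot"):
            raise ValueError("feature must be 'dc' or 'cdot'")
        if self.values.size < 2:
            raise ValueError("need at least two trials")
        if self.distribution == "uniform" and (
            self.values.min() < self.lo - 1e-12 or self.values.max() > self.hi + 1e-12
        ):
            raise ValueError("uniform samples must lie within [lo, hi]")

    @classmethod
    def uniform(
        cls,
        feature: str,
        n_trials: int = N_TRIALS_DEFAULT,
        lo: float = -0.01,
        hi: float = 0.01,
        seed: int = 0,
    ) -> "StimulusEnsemble":
        rng = np.random.default_rng(seed)
        return cls(feature, rng.uniform(lo, hi, n_trials), "uniform", lo, hi)

    @classmethod
    def empirical(
        cls, feature: str, samples: np.ndarray, n_trials: int, seed: int = 0
    ) -> "StimulusEnsemble":
        """Resample trial stimuli from an empirical pool of perceived values."""
        rng = np.random.default_rng(seed)
        values = rng.choice(np.asarray(samples, dtype=float), size=n_trials)
        return cls(
            feature, values, "empirical", float(values.min()), float(values.max())
        )


@dataclass
class Recording:
    """Trial x time x variable traces from repeated stimulus presentations."""

    stimulus: np.ndarray  # (n_trials,)
    traces: np.ndarray  # (n_trials, n_steps, n_variables)
    dt: float
    variables: tuple[str, ...] = OBSERVABLES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.traces.shape[0] != self.stimulus.shape[0]:
            raise ValueError("trial counts of stimulus and traces differ")
        if self.traces.shape[2] != len(self.variables):
            raise ValueError("variable axis does not match variable names")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.stimulus.shape[0]

    @property
    def n_steps(self) -> int:
        return self.traces.shape[1]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def trace(self, variable: str) -> np.ndarray:
        """(n_trials, n_steps) trace of one observable."""
        try:
            idx = self.variables.index(variable)
        except ValueError:
            raise KeyError(
                f"unknown variable {variable!r}; have {self.variables}"
            ) from None
        return self.traces[:, :, idx]

    # ------------------------------ HDF5 ------------------------------ #

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("stimulus", data=self.stimulus)
            f.create_dataset("traces", data=self.traces)
            f.attrs["dt"] = self.dt
            f.attrs["variables"] = list(self.variables)
            for key, value in self.meta.items():
                f.attrs[f"meta_{key}"] = value

    @classmethod
    def load(cls, path: str | Path) -> "Recording":
        import h5py

        with h5py.File(path, "r") as f:
            meta = {
                k[5:]: (v.item() if hasattr(v, "item") else v)
                for k, v in f.attrs.items()
                if k.startswith("meta_")
            }
            return cls(
                stimulus=f["stimulus"][:],
                traces=f["traces"][:],
                dt=float(f.attrs["dt"]),
                variables=tuple(str(v) for v in f.attrs["variables"]),
                meta=meta,
            )


def _settle_steps(params: CircuitParams, settle_cycles: float, dt: float) -> int:
    n = int(round(settle_cycles * params.T / dt))
    if n < params.N + params.M:
        raise ValueError(
            "stimulus onset before warm-up complete: settle window shorter "
            f"than the sensory history ({params.N + params.M} steps)"
        )
    return n


def concentration_step_assay(
    params: CircuitParams,
    ens: StimulusEnsemble,
    lesions: LesionSet = NO_LESION,
    record_cycles: float = 2.0,
    onset_phase: float = 0.0,
    settle_cycles: float = 6.0,
    dt: float = DT,
) -> Recording:
    """Record the response ensemble to concentration steps.

    Each trial runs at the baseline concentration until the circuit settles
    onto its unstimulated attractor, then the concentration jumps by the
    trial's delta-c.  ``onset_phase`` fixes the pattern-generator phase (of
    the ventral drive) at stimulus onset.  The recording window starts at
    onset and spans ``record_cycles`` locomotion cycles (default two).
    """
    if ens.feature != "dc":
        raise ValueError("concentration step assay needs a 'dc' ensemble")
    n_settle = _settle_steps(params, settle_cycles, dt)
    n_record = int(round(record_cycles * params.T / dt))
    n = len(ens.values)
    conc = np.full((n, n_settle + n_record), BASELINE_CONCENTRATION)
    conc[:, n_settle:] += ens.values[:, None]
    phase0 = onset_phase - 2.0 * np.pi * (n_settle * dt) / params.T
    traces = simulate_open_loop(
        params, conc, dt=dt, lesions=lesions, phase0=phase0, record_from=n_settle
    )
    return Recording(
        stimulus=ens.values.copy(),
        traces=traces,
        dt=dt,
        meta={
            "assay": "step",
            "feature": "dc",
            "period": params.T,
            "distribution": ens.distribution,
            "lesions": lesions.describe(),
            "onset_phase": onset_phase,
            "stim_lo": ens.lo,
            "stim_hi": ens.hi,
        },
    )


def information_clamp_assay(
    params: CircuitParams,
    ens: StimulusEnsemble,
    lesions: LesionSet = NO_LESION,
    record_cycles: float = 1.0,
    onset_phase: float = 0.0,
    settle_cycles: float = 6.0,
    transient_cycles: float = 2.0,
    dt: float = DT,
) -> Recording:
    """Record the response ensemble to constant rates of concentration change.

    Each trial ramps the concentration linearly at the trial's c-dot (per
    second).  The sensory derivative settles to the constant
    ``cdot * dt * (N + M) / 2`` after N+M steps; that settling window plus
    ``transient_cycles`` locomotion cycles are excluded, then one cycle
    (default) is recorded.  ``onset_phase`` fixes the PG phase at the start
    of the recorded window.
    """
    if ens.feature != "cdot":
        raise ValueError("information clamp assay needs a 'cdot' ensemble")
    p = params
    n_settle = _settle_steps(p, settle_cycles, dt)
    n_transient = p.N + p.M + int(round(transient_cycles * p.T / dt))
    n_record = int(round(record_cycles * p.T / dt))
    n_total = n_settle + n_transient + n_record
    n = len(ens.values)
    t_rel = (np.arange(n_total) - n_settle) * dt  # time since ramp onset
    ramp = np.where(t_rel > 0, t_rel, 0.0)
    conc = BASELINE_CONCENTRATION + ens.values[:, None] * ramp[None, :]
    rec_start = n_settle + n_transient
    phase0 = onset_phase - 2.0 * np.pi * (rec_start * dt) / p.T
    traces = simulate_open_loop(
        params, conc, dt=dt, lesions=lesions, phase0=phase0, record_from=rec_start
    )
    return Recording(
        stimulus=ens.values.copy(),
        traces=traces,
        dt=dt,
        meta={
            "assay": "clamp",
            "feature": "cdot",
            "period": params.T,
            "distribution": ens.distribution,
            "lesions": lesions.describe(),
            "onset_phase": onset_phase,
            "stim_lo": ens.lo,
            "stim_hi": ens.hi,
        },
    )


def phase_sweep(
    params: CircuitParams,
    ens: StimulusEnsemble,
    n_phases: int = 16,
    lesions: LesionSet = NO_LESION,
    record_cycles: float = 2.0,
    settle_cycles: float = 6.0,
    dt: float = DT,
    endpoint: bool = False,
) -> list[tuple[float, Recording]]:
    """Step assays at evenly spaced stimulus-onset phases.

    Returns a list of (onset_phase, Recording) pairs with phases spanning
    [0, 2*pi); with ``endpoint`` the closing phase 2*pi is included as well
    (it repeats phase 0 by periodicity).
    """
    if n_phases < 1:
        raise ValueError("need at least one phase")
    phases = np.linspace(0.0, 2.0 * np.pi, n_phases, endpoint=endpoint)
    out = []
    for phase in phases:
        rec = concentration_step_assay(
            params,
            ens,
            lesions=lesions,
            record_cycles=record_cycles,
            onset_phase=float(phase),
            settle_cycles=settle_cycles,
            dt=dt,
        )
        out.append((float(phase), rec))
    return out
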