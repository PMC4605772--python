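"""Minimal salt-klinotaxis circuit of *C. elegans*.

The model connects the two idealized ASE chemosensors (an ON cell responding
to concentration increases and an OFF cell responding to decreases) through
two layers of passive, isopotential interneurons (AIYL/R, AIZL/R) to the four
SMB neck motor neurons (SMBDL/DR/VL/VR), which drive the neck-angle velocity.
Chemical synapses are sigmoidal functions of presynaptic potential; left and
right cells within the AIY and AIZ layers are coupled by non-rectifying gap
junctions.  The motor neurons additionally receive a sinusoidal
pattern-generator (PG) drive of period ``T`` delivered in antiphase to the
dorsal and ventral cells, modelling the undulatory locomotion wave.  The body
is a single point moving at constant speed ``v`` whose heading integrates the
neck-angle velocity.

Integration is explicit Euler with step ``dt`` (default 0.01 s); the sensory
"derivative" is a windowed difference of the mean concentration over the
newest N samples and the preceding M samples of the concentration history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "CELLS",
    "OBSERVABLES",
    "DT",
    "LesionSet",
    "CircuitParams",
    "CircuitState",
    "sigmoid",
    "synapse",
    "sensor_derivative",
    "sensor_outputs",
    "neck_velocity",
    "step_circuit",
    "simulate_open_loop",
    "trajectory_frame",
]

#: integration step in seconds (exposed; all assays use this default)
DT = 0.01

#: interneuron / motor-neuron names, fixed order used throughout
CELLS = ("AIYL", "AIYR", "AIZL", "AIZR", "SMBDL", "SMBDR", "SMBVL", "SMBVR")

#: variables observed by the open-loop assays: the two chemosensor potentials,
#: the synaptic output of each neural cell, and the neck-angle velocity phi
OBSERVABLES = (
    "V_ON",
    "V_OFF",
    "sigma_AIYL",
    "sigma_AIYR",
    "sigma_AIZL",
    "sigma_AIZR",
    "sigma_SMBDL",
    "sigma_SMBDR",
    "sigma_SMBVL",
    "sigma_SMBVR",
    "phi",
)


@dataclass(frozen=True)
class LesionSet:
    """Circuit lesions: blocked gap junctions (coupling term set to zero)."""

    block_gap_AIY: bool = False
    block_gap_AIZ: bool = False

    def describe(self) -> str:
        parts = []
        if self.block_gap_AIY:
            parts.append("gap:AIY")
        if self.block_gap_AIZ:
            parts.append("gap:AIZ")
        return "+".join(parts) if parts else "none"


NO_LESION = LesionSet()


@dataclass
class CircuitParams:
    """All constants of one model circuit.

    Evolvable quantities: the sensory window lengths ``N``/``M`` (in
    integration steps), the shared membrane time constant ``tau`` (s), the
    chemical synaptic weights ``w_*``, the gap-junction conductances
    ``g_AIY``/``g_AIZ`` (> 0), the biases ``theta_*``, the pattern-generator
    weight ``w_PG`` and the neuromuscular weight ``w_NMJ``.  Fixed: the
    locomotion period ``T`` = 4.2 s and forward speed ``v`` = 0.022 cm/s.
    """

    N: int
    M: int
    tau: float
    # ASE -> AIY chemical synapses
    w_ON_AIYL: float
    w_ON_AIYR: float
    w_OFF_AIYL: float
    w_OFF_AIYR: float
    # AIY -> AIZ chemical synapses (ipsilateral)
    w_AIYL_AIZL: float
    w_AIYR_AIZR: float
    # AIZ -> SMB chemical synapses (ipsilateral, dorsal and ventral targets)
    w_AIZL_SMBDL: float
    w_AIZL_SMBVL: float
    w_AIZR_SMBDR: float
    w_AIZR_SMBVR: float
    # SMB self-connections (voltage dependence of inward currents)
    w_SMBDL_self: float
    w_SMBDR_self: float
    w_SMBVL_self: float
    w_SMBVR_self: float
    # gap junctions
    g_AIY: float
    g_AIZ: float
    # biases
    theta_AIYL: float
    theta_AIYR: float
    theta_AIZL: float
    theta_AIZR: float
    theta_SMBDL: float
    theta_SMBDR: float
    theta_SMBVL: float
    theta_SMBVR: float
    # drive weights
    w_PG: float
    w_NMJ: float
    # fixed constants
    T: float = 4.2
    v: float = 0.022
    dv_symmetric: bool = True

    # ------------------------------------------------------------------ #

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.N < 1 or self.M < 1:
            raise ValueError("sensory windows require N >= 1 and M >= 1")
        if not (self.tau > 0 and self.T > 0 and self.v > 0):
            raise ValueError("tau, T and v must be positive")
        if not (self.g_AIY > 0 and self.g_AIZ > 0):
            raise ValueError("gap-junction conductances must satisfy g > 0")
        if self.dv_symmetric and not self.is_dv_symmetric():
            raise ValueError(
                "dv_symmetric is set but dorsal/ventral parameters differ"
            )

    def is_dv_symmetric(self, tol: float = 0.0) -> bool:
        pairs = [
            (self.theta_SMBDL, self.theta_SMBVL),
            (self.theta_SMBDR, self.theta_SMBVR),
            (self.w_AIZL_SMBDL, self.w_AIZL_SMBVL),
            (self.w_AIZR_SMBDR, self.w_AIZR_SMBVR),
            (self.w_SMBDL_self, self.w_SMBVL_self),
            (self.w_SMBDR_self, self.w_SMBVR_self),
        ]
        return all(abs(a - b) <= tol for a, b in pairs)

    def chem_weights(self) -> dict[tuple[str, str], float]:
        """Chemical synaptic weights as a (pre, post) -> w map."""
        return {
            ("ON", "AIYL"): self.w_ON_AIYL,
            ("ON", "AIYR"): self.w_ON_AIYR,
            ("OFF", "AIYL"): self.w_OFF_AIYL,
            ("OFF", "AIYR"): self.w_OFF_AIYR,
            ("AIYL", "AIZL"): self.w_AIYL_AIZL,
            ("AIYR", "AIZR"): self.w_AIYR_AIZR,
            ("AIZL", "SMBDL"): self.w_AIZL_SMBDL,
            ("AIZL", "SMBVL"): self.w_AIZL_SMBVL,
            ("AIZR", "SMBDR"): self.w_AIZR_SMBDR,
            ("AIZR", "SMBVR"): self.w_AIZR_SMBVR,
            ("SMBDL", "SMBDL"): self.w_SMBDL_self,
            ("SMBDR", "SMBDR"): self.w_SMBDR_self,
            ("SMBVL", "SMBVL"): self.w_SMBVL_self,
            ("SMBVR", "SMBVR"): self.w_SMBVR_self,
        }

    def theta(self) -> dict[str, float]:
        return {c: getattr(self, f"theta_{c}") for c in CELLS}

    def mirror_lr(self) -> "CircuitParams":
        """Return the circuit with left and right labels swapped everywhere."""
        swap = {}
        # self-weights: w_SMBDL_self <-> w_SMBDR_self etc.
        for d in ("D", "V"):
            swap[f"w_SMB{d}L_self"] = getattr(self, f"w_SMB{d}R_self")
            swap[f"w_SMB{d}R_self"] = getattr(self, f"w_SMB{d}L_self")
        # synapse names encode both pre and post; rebuild explicitly
        swap["w_ON_AIYL"] = self.w_ON_AIYR
        swap["w_ON_AIYR"] = self.w_ON_AIYL
        swap["w_OFF_AIYL"] = self.w_OFF_AIYR
        swap["w_OFF_AIYR"] = self.w_OFF_AIYL
        swap["w_AIYL_AIZL"] = self.w_AIYR_AIZR
        swap["w_AIYR_AIZR"] = self.w_AIYL_AIZL
        swap["w_AIZL_SMBDL"] = self.w_AIZR_SMBDR
        swap["w_AIZL_SMBVL"] = self.w_AIZR_SMBVR
        swap["w_AIZR_SMBDR"] = self.w_AIZL_SMBDL
        swap["w_AIZR_SMBVR"] = self.w_AIZL_SMBVL
        for c in CELLS:
            other = c[:-1] + ("R" if c.endswith("L") else "L")
            swap[f"theta_{c}"] = getattr(self, f"theta_{other}")
        return replace(self, **swap)

    # -------------------------- serialization ------------------------- #

    def to_file(self, path: str | Path) -> None:
        """Write as a flat ``key = value`` text file (one key per line)."""
        lines = ["# klinfo circuit parameter file"]
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "CircuitParams":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def from_text(cls, text: str) -> "CircuitParams":
        kwargs: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in ("N", "M"):
                kwargs[key] = int(value)
            elif key == "dv_symmetric":
                kwargs[key] = value in ("True", "true", "1")
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class CircuitState:
    """Instantaneous state of a simulated circuit plus body point."""

    conc_history: np.ndarray  # oldest -> newest, length N+M
    V: dict[str, float]
    V_ON: float = 0.0
    V_OFF: float = 0.0
    t: float = 0.0
    mu: float = 0.0
    phi: float = 0.0
    x: float = 0.0
    y: float = 0.0
    phase0: float = 0.0  # PG phase offset at t = 0

    @classmethod
    def initial(
        cls,
        params: CircuitParams,
        c0: float = 1.0,
        phase0: float = 0.0,
    ) -> "CircuitState":
        """All potentials zero, history pre-filled with ``c0`` so d = 0."""
        hist = np.full(params.N + params.M, float(c0))
        return cls(conc_history=hist, V={c: 0.0 for c in CELLS}, phase0=phase0)


# ---------------------------------------------------------------------- #
# elementary operations
# ---------------------------------------------------------------------- #


def sigmoid(x):
    """Logistic function sigma(x) = 1 / (1 + exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def synapse(x, theta):
    """Synaptic output sigma(x + theta) in (0, 1)."""
    return sigmoid(np.asarray(x, dtype=float) + theta)


def sensor_derivative(history, N: int, M: int):
    """Windowed concentration derivative.

    Mean of the newest ``N`` samples minus the mean of the ``M`` samples
    preceding them.  ``history`` is ordered oldest -> newest along its last
    axis and must hold at least N+M samples.
    """
    if N < 1 or M < 1:
        raise ValueError("N and M must be >= 1")
    h = np.asarray(history, dtype=float)
    if h.shape[-1] == 0:
        raise ValueError("empty concentration history")
    if h.shape[-1] < N + M:
        raise ValueError(
            f"history holds {h.shape[-1]} samples; needs at least N+M={N + M}"
        )
    newest = h[..., -N:].mean(axis=-1)
    previous = h[..., -(N + M):-N].mean(axis=-1)
    return newest - previous


def sensor_outputs(d):
    """Idealized ON/OFF chemosensor potentials for derivative ``d``.

    V_ON = d when d > 0 else 0; V_OFF = -d when d <= 0 else 0.  At most one
    of the two is nonzero at any instant.
    """
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite concentration derivative")
    v_on = np.where(d > 0, d, 0.0)
    v_off = np.where(d > 0, 0.0, -d)
    return v_on, v_off


def neck_velocity(smb_sigma, w_NMJ: float):
    """Neck-angle velocity from the four SMB synaptic outputs.

    ``smb_sigma`` is (sigma_SMBDL, sigma_SMBDR, sigma_SMBVL, sigma_SMBVR);
    phi = w_NMJ * ((dorsal sum) - (ventral sum)).
    """
    sdl, sdr, svl, svr = smb_sigma
    return w_NMJ * ((sdl + sdr) - (svl + svr))


# ---------------------------------------------------------------------- #
# single-step integration (scalar reference path)
# ---------------------------------------------------------------------- #


def _gap(g: float, blocked: bool) -> float:
    return 0.0 if blocked else g


def step_circuit(
    state: CircuitState,
    params: CircuitParams,
    c_t: float,
    dt: float = DT,
    lesions: LesionSet = NO_LESION,
) -> CircuitState:
    """Advance the full circuit + body state by one Euler step.

    ``c_t`` is the concentration at the state's *current* time ``t``.  The
    step appends it to the history, evaluates all instantaneous quantities at
    time ``t`` (sensory derivative, chemosensor outputs, synaptic outputs,
    neck-angle velocity), then advances the membrane potentials, heading and
    position to ``t + dt``.  The returned state stores the time-``t``
    observables (``V_ON``, ``V_OFF``, ``phi``) alongside the advanced
    potentials, matching the recording convention of
    :func:`simulate_open_loop`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for name, value in state.V.items():
        if not math.isfinite(value):
            raise ValueError(f"non-finite membrane potential in {name}")
    p = params
    hist = np.roll(state.conc_history, -1)
    hist[-1] = c_t
    d = float(sensor_derivative(hist, p.N, p.M))
    v_on, v_off = sensor_outputs(d)
    v_on, v_off = float(v_on), float(v_off)

    V = state.V
    s = {c: float(synapse(V[c], getattr(p, f"theta_{c}"))) for c in CELLS}
    g_aiy = _gap(p.g_AIY, lesions.block_gap_AIY)
    g_aiz = _gap(p.g_AIZ, lesions.block_gap_AIZ)
    pg = math.sin(2.0 * math.pi * state.t / p.T + state.phase0)

    dV = {
        "AIYL": -V["AIYL"] + p.w_ON_AIYL * v_on + p.w_OFF_AIYL * v_off
        + g_aiy * (V["AIYR"] - V["AIYL"]),
        "AIYR": -V["AIYR"] + p.w_ON_AIYR * v_on + p.w_OFF_AIYR * v_off
        + g_aiy * (V["AIYL"] - V["AIYR"]),
        "AIZL": -V["AIZL"] + p.w_AIYL_AIZL * s["AIYL"]
        + g_aiz * (V["AIZR"] - V["AIZL"]),
        "AIZR": -V["AIZR"] + p.w_AIYR_AIZR * s["AIYR"]
        + g_aiz * (V["AIZL"] - V["AIZR"]),
        # ventral cells receive +w_PG*sin, dorsal cells the antiphase signal
        "SMBDL": -V["SMBDL"] + p.w_AIZL_SMBDL * s["AIZL"]
        + p.w_SMBDL_self * s["SMBDL"] - p.w_PG * pg,
        "SMBDR": -V["SMBDR"] + p.w_AIZR_SMBDR * s["AIZR"]
        + p.w_SMBDR_self * s["SMBDR"] - p.w_PG * pg,
        "SMBVL": -V["SMBVL"] + p.w_AIZL_SMBVL * s["AIZL"]
        + p.w_SMBVL_self * s["SMBVL"] + p.w_PG * pg,
        "SMBVR": -V["SMBVR"] + p.w_AIZR_SMBVR * s["AIZR"]
        + p.w_SMBVR_self * s["SMBVR"] + p.w_PG * pg,
    }
    phi = float(
        neck_velocity((s["SMBDL"], s["SMBDR"], s["SMBVL"], s["SMBVR"]), p.w_NMJ)
    )
    newV = {c: V[c] + dt / p.tau * dV[c] for c in CELLS}
    return CircuitState(
        conc_history=hist,
        V=newV,
        V_ON=v_on,
        V_OFF=v_off,
        t=state.t + dt,
        mu=state.mu + dt * phi,
        phi=phi,
        x=state.x + dt * p.v * math.cos(state.mu),
        y=state.y + dt * p.v * math.sin(state.mu),
        phase0=state.phase0,
    )


# ---------------------------------------------------------------------- #
# vectorized open-loop simulation (trials axis)
# ---------------------------------------------------------------------- #


def simulate_open_loop(
    params: CircuitParams,
    conc: np.ndarray,
    dt: float = DT,
    lesions: LesionSet = NO_LESION,
    phase0: float = 0.0,
    record_from: int = 0,
) -> np.ndarray:
    """Simulate the circuit open-loop on prescribed concentration series.

    ``conc`` has shape (n_trials, n_steps); trial ``i`` experiences
    concentration ``conc[i, k]`` at time ``k * dt``.  The history buffer is
    pre-filled with ``conc[:, 0]`` so the derivative starts at zero.  Returns
    the observable traces with shape (n_trials, n_steps - record_from,
    len(OBSERVABLES)); sample ``k`` holds the observables at time
    ``(record_from + k) * dt`` *after* the concentration at that time has
    entered the history.

    Observable convention: V_ON/V_OFF and phi at step ``k`` are instantaneous
    functions of the history and potentials at step ``k``; the potentials are
    the result of integrating through step ``k-1``.
    """
    p = params
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    n, n_steps = conc.shape
    NM = p.N + p.M
    # circular history buffer plus incremental window sums:
    # sum_N over samples (k-N, k], sum_M over samples (k-N-M, k-N]
    hist = np.repeat(conc[:, :1], NM, axis=1).astype(float)  # (n, N+M)
    sum_N = hist[:, 0] * p.N
    sum_M = hist[:, 0] * p.M
    V = np.zeros((8, n))
    thetas = np.array([getattr(p, f"theta_{c}") for c in CELLS])[:, None]
    g_aiy = _gap(p.g_AIY, lesions.block_gap_AIY)
    g_aiz = _gap(p.g_AIZ, lesions.block_gap_AIZ)
    out = np.empty((n, n_steps - record_from, len(OBSERVABLES)))

    for k in range(n_steps):
        x_new = conc[:, k]
        boundary = hist[:, (k - p.N) % NM]  # sample k-N leaves the N window
        oldest = hist[:, k % NM]            # sample k-N-M leaves the M window
        sum_N = sum_N + (x_new - boundary)
        sum_M = sum_M + (boundary - oldest)
        hist[:, k % NM] = x_new
        d = sum_N / p.N - sum_M / p.M
        v_on = np.where(d > 0, d, 0.0)
        v_off = np.where(d > 0, 0.0, -d)

        sig = 1.0 / (1.0 + np.exp(-(V + thetas)))
        phi = p.w_NMJ * ((sig[4] + sig[5]) - (sig[6] + sig[7]))

        if k >= record_from:
            j = k - record_from
            out[:, j, 0] = v_on
            out[:, j, 1] = v_off
            out[:, j, 2:10] = sig.T
            out[:, j, 10] = phi

        pg = math.sin(2.0 * math.pi * (k * dt) / p.T + phase0)
        dV = np.empty_like(V)
        dV[0] = -V[0] + p.w_ON_AIYL * v_on + p.w_OFF_AIYL * v_off + g_aiy * (V[1] - V[0])
        dV[1] = -V[1] + p.w_ON_AIYR * v_on + p.w_OFF_AIYR * v_off + g_aiy * (V[0] - V[1])
        dV[2] = -V[2] + p.w_AIYL_AIZL * sig[0] + g_aiz * (V[3] - V[2])
        dV[3] = -V[3] + p.w_AIYR_AIZR * sig[1] + g_aiz * (V[2] - V[3])
        dV[4] = -V[4] + p.w_AIZL_SMBDL * sig[2] + p.w_SMBDL_self * sig[4] - p.w_PG * pg
        dV[5] = -V[5] + p.w_AIZR_SMBDR * sig[3] + p.w_SMBDR_self * sig[5] - p.w_PG * pg
        dV[6] = -V[6] + p.w_AIZL_SMBVL * sig[2] + p.w_SMBVL_self * sig[6] + p.w_PG * pg
        dV[7] = -V[7] + p.w_AIZR_SMBVR * sig[3] + p.w_SMBVR_self * sig[7] + p.w_PG * pg
        V = V + (dt / p.tau) * dV
        if not np.all(np.isfinite(V)):
            bad = int(np.argwhere(~np.isfinite(V))[0][0])
            raise FloatingPointError(
                f"non-finite membrane potential in {CELLS[bad]} at step {k}"
            )
    return out


def trajectory_frame(states: Iterable[CircuitState], params: CircuitParams):
    """Tabulate a sequence of states as a tidy trajectory table."""
    import pandas as pd

    rows = []
    for st in states:
        row = {
            "t": st.t,
            "c": float(st.conc_history[-1]),
            "d": float(sensor_derivative(st.conc_history, params.N, params.M)),
            "V_ON": st.V_ON,
            "V_OFF": st.V_OFF,
        }
        for c in CELLS:
            row[f"V_{c}"] = st.V[c]
        for c in CELLS:
            row[f"sigma_{c}"] = float(synapse(st.V[c], getattr(params, f"theta_{c}")))
        row.update({"phi": st.phi, "mu": st.mu, "x": st.x, "y": st.y})
        rows.append(row)
    return pd.DataFrame(rows)
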