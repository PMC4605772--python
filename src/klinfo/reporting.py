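"""Derived summaries: information architecture, gating, timing, ensembles.

The information architecture condenses the time-resolved analysis into a
graph: each cell carries its time-averaged normalized mutual information
about the stimulus and the split of its specific information between
positive and negative concentration changes; each anatomical connection
carries the time-averaged transfer entropy flowing along it.  Sensor and
interneuron quantities come from the concentration step assay; motor and
neck quantities from the information clamp assay, which removes the
trivial phase dependence of the step response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assays import Recording
from .circuit import CELLS, CircuitParams
from .info import (
    DEFAULT_BINS,
    DEFAULT_SHIFTS,
    InfoProfile,
    mi_profile,
    specific_info_profile,
    te_profile,
)

__all__ = [
    "NODE_VARIABLES",
    "CHEMICAL_EDGES",
    "GAP_EDGES",
    "InfoArchitecture",
    "TimingMetrics",
    "build_architecture",
    "symmetry_index",
    "gating_curves",
    "timing_metrics",
    "ensemble_report",
]

#: graph node -> observed variable
NODE_VARIABLES = {
    "ASEL": "V_ON",
    "ASER": "V_OFF",
    **{c: f"sigma_{c}" for c in CELLS},
    "neck": "phi",
}

#: directed chemical-synapse edges of the wiring diagram
CHEMICAL_EDGES = (
    ("ASEL", "AIYL"), ("ASEL", "AIYR"), ("ASER", "AIYL"), ("ASER", "AIYR"),
    ("AIYL", "AIZL"), ("AIYR", "AIZR"),
    ("AIZL", "SMBDL"), ("AIZL", "SMBVL"), ("AIZR", "SMBDR"), ("AIZR", "SMBVR"),
    ("SMBDL", "neck"), ("SMBDR", "neck"), ("SMBVL", "neck"), ("SMBVR", "neck"),
)

#: gap junctions, represented as two directed edges each
GAP_EDGES = (
    ("AIYL", "AIYR"), ("AIYR", "AIYL"), ("AIZL", "AIZR"), ("AIZR", "AIZL"),
)

#: nodes whose analysis uses the information clamp assay
_CLAMP_NODES = frozenset({"SMBDL", "SMBDR", "SMBVL", "SMBVR", "neck"})


@dataclass
class InfoArchitecture:
    """Graph summary of a circuit's information flow."""

    nodes: dict  # name -> {mi, pos, neg, assay}
    edges: dict  # "src->dst" -> {te, te_bits, kind, assay}
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"nodes": self.nodes, "edges": self.edges, "meta": self.meta},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "InfoArchitecture":
        p = Path(str(text_or_path))
        text = p.read_text() if p.is_file() else str(text_or_path)
        obj = json.loads(text)
        return cls(nodes=obj["nodes"], edges=obj["edges"], meta=obj.get("meta", {}))

    def to_graphml(self, path: str | Path) -> None:
        lines = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
            '<key id="mi" for="node" attr.name="mi" attr.type="double"/>',
            '<key id="pos" for="node" attr.name="pos" attr.type="double"/>',
            '<key id="te" for="edge" attr.name="te" attr.type="double"/>',
            '<graph edgedefault="directed">',
        ]
        for name, attrs in self.nodes.items():
            lines.append(
                f'<node id="{name}"><data key="mi">{attrs["mi"]}</data>'
                f'<data key="pos">{attrs["pos"]}</data></node>'
            )
        for key, attrs in self.edges.items():
            src, dst = key.split("->")
            lines.append(
                f'<edge source="{src}" target="{dst}">'
                f'<data key="te">{attrs["te"]}</data></edge>'
            )
        lines += ["</graph>", "</graphml>"]
        Path(path).write_text("\n".join(lines))


def _posneg_split(surface: np.ndarray, centres: np.ndarray) -> tuple[float, float]:
    """Fraction of time-averaged specific information on s > 0 vs s < 0."""
    mean_si = np.nanmean(surface, axis=0)
    pos = float(np.nansum(np.clip(mean_si[centres > 0], 0.0, None)))
    neg = float(np.nansum(np.clip(mean_si[centres < 0], 0.0, None)))
    total = pos + neg
    if total <= 0:
        return 0.5, 0.5
    return pos / total, neg / total


def build_architecture(
    params: CircuitParams,
    step_rec: Recording,
    clamp_rec: Recording,
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
) -> InfoArchitecture:
    """Assemble the information-architecture graph from the two assays.

    Node opacity-equivalents are time-averaged normalized MI; node color
    splits come from the sign structure of time-averaged specific
    information; edge weights are time-averaged transfer entropy along the
    anatomical connections.
    """
    for rec, label in ((step_rec, "step"), (clamp_rec, "clamp")):
        if rec.meta.get("assay") != label:
            raise ValueError(f"expected a {label} recording")
    nodes: dict = {}
    profiles: dict[str, InfoProfile] = {}
    for name, var in NODE_VARIABLES.items():
        rec = clamp_rec if name in _CLAMP_NODES else step_rec
        if var not in rec.variables:
            raise KeyError(f"recording lacks variable {var!r} for node {name}")
        prof = mi_profile(rec, var, bins=bins, shifts=shifts)
        surface, centres, _ = specific_info_profile(rec, var, bins=bins, shifts=shifts)
        pos, neg = _posneg_split(surface, centres)
        profiles[name] = prof
        nodes[name] = {
            "mi": prof.time_average(normalized=True),
            "pos": pos,
            "neg": neg,
            "assay": rec.meta.get("assay", ""),
        }
    edges: dict = {}
    for kind, edge_list in (("chemical", CHEMICAL_EDGES), ("gap", GAP_EDGES)):
        for src, dst in edge_list:
            rec = clamp_rec if dst in _CLAMP_NODES else step_rec
            prof = te_profile(
                rec, NODE_VARIABLES[src], NODE_VARIABLES[dst], bins=bins, shifts=shifts
            )
            edges[f"{src}->{dst}"] = {
                "te": prof.time_average(normalized=True),
                "te_bits": prof.time_average(normalized=False),
                "kind": kind,
                "assay": rec.meta.get("assay", ""),
            }
    arch = InfoArchitecture(
        nodes=nodes,
        edges=edges,
        meta={
            "bins": bins,
            "shifts": shifts,
            "n_trials_step": step_rec.n_trials,
            "n_trials_clamp": clamp_rec.n_trials,
            "lesions": step_rec.meta.get("lesions", "none"),
        },
    )
    arch._profiles = profiles  # bookkeeping for consistency checks
    return arch


def symmetry_index(profile_left, profile_right) -> float:
    """Left/right informational symmetry in [0, 1].

    Ratio of the smaller to the larger time-averaged information of the two
    profiles: near 1 the cells carry similar information (symmetric), near
    0 one dominates (asymmetric).  Defined as 1 when both averages vanish.
    """
    a = np.atleast_1d(_mean_of(profile_left))
    b = np.atleast_1d(_mean_of(profile_right))
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    lo, hi = sorted((float(np.mean(a)), float(np.mean(b))))
    if hi <= 0:
        return 1.0
    return max(lo, 0.0) / hi


def _mean_of(profile) -> np.ndarray:
    if isinstance(profile, InfoProfile):
        return profile.normalized
    return np.asarray(profile, dtype=float)


def gating_curves(
    sweep: list[tuple[float, Recording]],
    delay: float = 0.05,
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
    average_cycles: float = 1.0,
):
    """Per-SMB-cell normalized MI versus stimulus-onset phase.

    For each onset phase, the mutual information of each SMB synaptic
    output is extracted at a fixed ``delay`` after the step (the
    saturating-gate picture) and also averaged over ``average_cycles``
    locomotion cycles of delays.  Returns (phases, fixed, averaged) where
    the latter two map cell name -> array over phases.
    """
    if len(sweep) < 1:
        raise ValueError("empty phase sweep")
    cells = ("SMBDL", "SMBDR", "SMBVL", "SMBVR")
    phases = np.array([ph for ph, _ in sweep])
    fixed = {c: np.empty(len(sweep)) for c in cells}
    averaged = {c: np.empty(len(sweep)) for c in cells}
    for k, (_, rec) in enumerate(sweep):
        delay_idx = int(round(delay / rec.dt))
        if delay_idx >= rec.n_steps:
            raise ValueError("delay exceeds the recorded window")
        T_cycle = rec.meta.get("period", None)
        n_avg = rec.n_steps
        if average_cycles is not None and T_cycle:
            n_avg = min(rec.n_steps, int(round(average_cycles * T_cycle / rec.dt)))
        for c in cells:
            prof = mi_profile(rec, f"sigma_{c}", bins=bins, shifts=shifts)
            fixed[c][k] = prof.normalized[delay_idx]
            averaged[c][k] = float(np.mean(prof.normalized[:n_avg]))
    return phases, fixed, averaged


@dataclass
class TimingMetrics:
    """Durations (s) read off threshold crossings of normalized MI.

    ``propagation_delay``: stimulus onset to first neck response;
    ``sensor_duration``: stimulus onset to end of the sensor response;
    ``persistence``: information outliving the sensor response elsewhere in
    the circuit; ``neck_duration``: total duration of the neck response.
    A metric is None when the corresponding crossing does not occur.
    """

    propagation_delay: float | None
    sensor_duration: float | None
    persistence: float | None
    neck_duration: float | None


def _first_above(values: np.ndarray, thr: float) -> int | None:
    idx = np.nonzero(values >= thr)[0]
    return int(idx[0]) if idx.size else None


def _last_above(values: np.ndarray, thr: float) -> int | None:
    idx = np.nonzero(values >= thr)[0]
    return int(idx[-1]) if idx.size else None


def timing_metrics(
    step_rec: Recording,
    threshold: float = 0.05,
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
) -> TimingMetrics:
    """Propagation and persistence timescales from a step recording.

    Uses the joint ASE-pair profile for the sensors and the neck-angle
    velocity profile for the output; onset/offset are the first/last
    crossings of ``threshold`` (normalized MI).
    """
    sensor = mi_profile(
        step_rec, ("V_ON", "V_OFF"), bins=bins, shifts=shifts
    ).normalized
    neck = mi_profile(step_rec, "phi", bins=bins, shifts=shifts).normalized
    dt = step_rec.dt
    b = _first_above(neck, threshold)
    c = _last_above(sensor, threshold)
    d = _last_above(neck, threshold)
    return TimingMetrics(
        propagation_delay=None if b is None else b * dt,
        sensor_duration=None if c is None else (c + 1) * dt,
        persistence=None if (c is None or d is None) else max(d - c, 0) * dt,
        neck_duration=None if (b is None or d is None) else (d - b + 1) * dt,
    )


def timing_sensitivity(
    step_rec: Recording,
    thresholds: tuple[float, ...] = (0.02, 0.05, 0.10),
    bins: int = DEFAULT_BINS,
    shifts: int = DEFAULT_SHIFTS,
) -> dict[float, TimingMetrics]:
    """Timing metrics across onset/offset thresholds (sensitivity report)."""
    return {
        thr: timing_metrics(step_rec, threshold=thr, bins=bins, shifts=shifts)
        for thr in thresholds
    }


def ensemble_report(circuit_profiles: list[dict[str, InfoProfile]]):
    """Mean and standard deviation of aligned ensemble profiles.

    ``circuit_profiles`` maps, per circuit, cell keys to MI profiles; the
    standard alignment convention is applied before averaging: the AIY cell
    with the higher cumulative information becomes ``AIY_hi`` (the other
    ``AIY_lo``); the AIZ cell downstream of the dominant AIY becomes
    ``AIZ_down``; SMB left/right pairs rank by cumulative information.  ASE
    and neck keys pass through unchanged.  Returns
    {aligned key: (mean array, sd array)} over normalized profiles.
    """
    if len(circuit_profiles) < 2:
        raise ValueError("need at least two circuits")
    aligned: dict[str, list[np.ndarray]] = {}

    def push(key: str, prof: InfoProfile) -> None:
        aligned.setdefault(key, []).append(prof.normalized)

    for profs in circuit_profiles:
        have = set(profs)
        if {"AIYL", "AIYR"} <= have:
            left_dominant = (
                profs["AIYL"].time_average() >= profs["AIYR"].time_average()
            )
            push("AIY_hi", profs["AIYL" if left_dominant else "AIYR"])
            push("AIY_lo", profs["AIYR" if left_dominant else "AIYL"])
            if {"AIZL", "AIZR"} <= have:
                push("AIZ_down", profs["AIZL" if left_dominant else "AIZR"])
                push("AIZ_other", profs["AIZR" if left_dominant else "AIZL"])
        if {"SMBL", "SMBR"} <= have:
            left_hi = profs["SMBL"].time_average() >= profs["SMBR"].time_average()
            push("SMB_hi", profs["SMBL" if left_hi else "SMBR"])
            push("SMB_lo", profs["SMBR" if left_hi else "SMBL"])
        for key in ("ASEL", "ASER", "neck"):
            if key in have:
                push(key, profs[key])
    out = {}
    for key, arrs in aligned.items():
        stack = np.vstack(arrs)
        out[key] = (stack.mean(axis=0), stack.std(axis=0))
    return out
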