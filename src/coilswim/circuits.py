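"""Construction of the developmental spinal circuit models.

Three families of models are built here, mirroring the locomotor milestones of
the developing zebrafish:

* ``single_coiling`` -- a rostral kernel of five recurrently coupled IC
  pacemakers drives ipsilateral chains of MNs and V0ds through gap junctions;
  V0ds project glycinergic synapses to contralateral MNs and ICs.
* ``double_coiling`` -- the same electrical scaffold plus V0vs (commissural
  glutamatergic, projecting to contralateral ICs) and V2as (ipsilateral
  descending glutamatergic, projecting to V0vs), with bilateral IC drive.
* ``beat_glide_*`` -- no pacemakers; 15 somites of MN/dI6/V0v/V2a/V1 per side
  with V2as driven tonically; rhythm and episode structure emerge from the
  network.  Variants: ``base`` (bursting V0vs), ``bursting_v2a`` and
  ``all_tonic``.

Connections carry conduction delays ``distance / cv`` computed from Euclidean
distance between the point neurons (somite length 1.6 a.d.u.).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .neurons import IzhikevichParams, PopulationSpec

__all__ = [
    "Connection",
    "CircuitModel",
    "euclidean_distance",
    "compute_delay",
    "load_params",
    "build_single_coiling",
    "build_double_coiling",
    "build_beat_and_glide",
    "build_model",
    "MODEL_FACTORIES",
    "export_connectome",
]

GAP = "gap"
GLUT = "glutamatergic"
GLY = "glycinergic"
NMJ = "neuromuscular"


@dataclass
class Connection:
    """A directed edge: gap junction, chemical synapse, or MN-to-muscle synapse.

    Gap junctions are stored directionally but always built in symmetric pairs
    with equal weight.  ``delay`` is the conduction delay in ms.
    """

    pre: int
    post: int
    kind: str
    weight: float
    delay: float
    reciprocal: bool = True  # gap junctions: conductance counted from both ends

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("connection weight must be non-negative")
        if self.delay < 0:
            raise ValueError("connection delay must be non-negative")


def euclidean_distance(x1: float, y1: float, x2: float, y2: float) -> float:
    """Distance between two point neurons in a.d.u."""
    return float(np.hypot(x2 - x1, y2 - y1))


def compute_delay(distance: float, cv: float) -> float:
    """Conduction delay (ms) for a given axonal distance and speed ``cv``.

    ``cv`` is the transmission speed in a.d.u. per millisecond (0.8 for the
    swimming model, which puts intersegmental delays in the 3-4 ms range).
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    return distance / cv


# ---------------------------------------------------------------------------
# connection rules


@dataclass(frozen=True)
class GapRule:
    """Electrical coupling rule between two ipsilateral populations.

    mode 'kernel'   : all-to-all within the (pre == post) population;
    mode 'block'    : every pre neuron couples the first ``extent`` members of
                      the post chain (IC kernel onto rostral chain segments);
    mode 'all'      : all-to-all between two distinct populations;
    mode 'neighbor' : members within ``extent`` segments of each other
                      (excluding the same segment for distinct populations).
    """

    pre: str
    post: str
    weight: float
    mode: str
    extent: int = 3
    reciprocal: bool = True  # pair listed from both endpoints (doubled conductance)


@dataclass(frozen=True)
class ChemRule:
    """Chemical projection rule.

    The pre neuron in segment i targets post neurons in segments
    ``i - asc .. i + desc`` (optionally including i), on the opposite side if
    ``contra``.  ``asc``/``desc`` of ``None`` mean "to the end of the body".
    ``noise_sd`` scales each realized weight by Gaussian(1, sd), clamped at 0.
    """

    pre: str
    post: str
    weight: float
    syn: str  # GLUT or GLY
    contra: bool
    asc: int | None = 0
    desc: int | None = 0
    include_same: bool = False
    noise_sd: float = 0.0


@dataclass
class CircuitModel:
    """A complete executable network: populations, connections, constants."""

    name: str
    populations: list[PopulationSpec]
    connections: list[Connection]
    muscle_synapses: list[Connection]
    n_somites: int
    somite_length: float
    cv: float
    dt: float
    e_glut: float
    e_gly: float
    tau_r: float
    tau_f: float
    v_thr: float
    muscle_R: float
    muscle_C: float
    mn_muscle_weight: float
    body: dict
    sheet: dict = field(repr=False, default_factory=dict)
    factory: str = ""
    factory_kwargs: dict = field(default_factory=dict)
    param_scales: np.ndarray | None = None  # (n_neurons, 9) multiplicative
    sigma_d: float = 0.0  # per-step Gaussian sd on the drive amplitude
    gap_mode: int = 3  # 0: (Vpre-Vpost)*G, 1: printed Vpre*G,
    #                    2: (Vpre-Vr_pre)*G, 3: ((Vpre-Vr_pre)-(Vpost-Vr_post))*G
    gap_scale: float = 2.0  # junction conductance applied from both endpoints
    chem_per_capacitance: bool = True  # chemical weights scale the voltage rate
    chem_sum_kernels: bool = False  # superpose kernels instead of renewal

    # -- indexing helpers ---------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return sum(p.count for p in self.populations)

    @property
    def n_muscle_cells(self) -> int:
        return self.n_somites

    def pop_slice(self, kind: str, side: str) -> slice:
        start = 0
        for p in self.populations:
            if p.kind == kind and p.side == side:
                return slice(start, start + p.count)
            start += p.count
        raise KeyError(f"no population {kind!r} on side {side!r}")

    def kinds(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            if p.kind not in seen:
                seen.append(p.kind)
        return seen

    def neuron_positions(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.concatenate([p.x for p in self.populations])
        y = np.concatenate([p.y for p in self.populations])
        return x, y

    def muscle_index(self, side: str, somite: int) -> int:
        """Global id of a muscle cell (1-based somite), after all neurons."""
        s = 0 if side == "left" else 1
        return self.n_neurons + s * self.n_muscle_cells + (somite - 1)

    def copy(self) -> "CircuitModel":
        m = copy.copy(self)
        m.connections = [replace(c) for c in self.connections]
        m.muscle_synapses = [replace(c) for c in self.muscle_synapses]
        if self.param_scales is not None:
            m.param_scales = self.param_scales.copy()
        m.factory_kwargs = dict(self.factory_kwargs)
        return m


# ---------------------------------------------------------------------------
# parameter sheets


def load_params(model_variant: str) -> dict:
    """Load the YAML parameter sheet for a named model variant."""
    ref = importlib.resources.files("coilswim") / "params" / f"{model_variant}.yaml"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown model variant {model_variant!r}") from None
    return yaml.safe_load(text)


def _apply_overrides(sheet: dict, overrides: dict | None) -> dict:
    """Deep-set dotted-path overrides, e.g. ``{'gap_weights.IC_MN': 0.05}``."""
    sheet = copy.deepcopy(sheet)
    for path, value in (overrides or {}).items():
        node = sheet
        keys = path.split(".")
        for key in keys[:-1]:
            if key not in node:
                raise KeyError(f"unknown override path {path!r}")
            node = node[key]
        if keys[-1] not in node:
            raise KeyError(f"unknown override path {path!r}")
        node[keys[-1]] = value
    return sheet


# ---------------------------------------------------------------------------
# realization of rules into connections


def _segment_range(
    seg: int, asc: int | None, desc: int | None, include_same: bool, n_seg: int
) -> np.ndarray:
    lo = 1 if asc is None else max(1, seg - asc)
    hi = n_seg if desc is None else min(n_seg, seg + desc)
    segs = np.arange(lo, hi + 1)
    if not include_same:
        segs = segs[segs != seg]
    return segs


def _scaled(extent: int | None, scale: float) -> int | None:
    if extent is None:
        return None
    return max(0, int(round(extent * scale)))


def _realize_connections(
    populations: list[PopulationSpec],
    gap_rules: list[GapRule],
    chem_rules: list[ChemRule],
    *,
    n_somites: int,
    cv: float,
    e_glut_chain_segments: int,
    rng: np.random.Generator,
    sigma_l: float = 0.0,
) -> list[Connection]:
    """Expand the rule lists into directed, delayed connections.

    ``sigma_l`` scales every pre-neuron's projection extents by independent
    Gaussian(1, sigma_l) draws (rounded to whole segments, clamped at 0),
    emulating variability in the rostrocaudal length of axonal projections.
    """
    del e_glut_chain_segments  # reserved
    index = {}
    start = 0
    for p in populations:
        index[(p.kind, p.side)] = (start, p)
        start += p.count
    x = np.concatenate([p.x for p in populations])
    y = np.concatenate([p.y for p in populations])

    def delay(i: int, j: int) -> float:
        return compute_delay(euclidean_distance(x[i], y[i], x[j], y[j]), cv)

    def ldraw() -> float:
        if sigma_l <= 0:
            return 1.0
        return max(0.0, 1.0 + sigma_l * rng.standard_normal())

    conns: list[Connection] = []

    for rule in gap_rules:
        if rule.weight <= 0:
            continue
        for side in ("left", "right"):
            pre_start, pre_pop = index[(rule.pre, side)]
            post_start, post_pop = index[(rule.post, side)]
            pairs: list[tuple[int, int]] = []
            if rule.mode == "kernel":
                for i in range(pre_pop.count):
                    for j in range(post_pop.count):
                        if i != j:
                            pairs.append((pre_start + i, post_start + j))
            elif rule.mode == "all":
                for i in range(pre_pop.count):
                    for j in range(post_pop.count):
                        gi, gj = pre_start + i, post_start + j
                        pairs.append((gi, gj))
                        pairs.append((gj, gi))
            elif rule.mode == "block":
                for i in range(pre_pop.count):
                    k = _scaled(rule.extent, ldraw())
                    for j in range(min(k, post_pop.count)):
                        gi, gj = pre_start + i, post_start + j
                        pairs.append((gi, gj))
                        pairs.append((gj, gi))
            elif rule.mode == "neighbor":
                segs_pre = pre_pop.segments()
                segs_post = post_pop.segments()
                same = rule.pre == rule.post
                for i in range(pre_pop.count):
                    ext = _scaled(rule.extent, ldraw())
                    for j in range(post_pop.count):
                        dseg = abs(int(segs_pre[i]) - int(segs_post[j]))
                        if dseg == 0 or dseg > ext:
                            continue
                        gi, gj = pre_start + i, post_start + j
                        pairs.append((gi, gj))
                        if not same:
                            pairs.append((gj, gi))
            else:  # pragma: no cover - guarded by construction
                raise ValueError(f"unknown gap rule mode {rule.mode!r}")
            for gi, gj in pairs:
                c = Connection(gi, gj, GAP, rule.weight, delay(gi, gj))
                c.reciprocal = rule.reciprocal
                conns.append(c)

    syn_kind = {"glut": GLUT, "gly": GLY}
    for rule in chem_rules:
        if rule.weight <= 0:
            continue
        for pre_side in ("left", "right"):
            post_side = (
                {"left": "right", "right": "left"}[pre_side]
                if rule.contra
                else pre_side
            )
            pre_start, pre_pop = index[(rule.pre, pre_side)]
            post_start, post_pop = index[(rule.post, post_side)]
            segs_post = post_pop.segments()
            for i in range(pre_pop.count):
                seg = int(pre_pop.segments()[i])
                asc = _scaled(rule.asc, ldraw())
                desc = _scaled(rule.desc, ldraw())
                if post_pop.kind == "IC":
                    targets = np.arange(post_pop.count)  # rostral kernel: all
                else:
                    segs = _segment_range(
                        seg, asc, desc, rule.include_same, n_somites + 1
                    )
                    targets = np.where(np.isin(segs_post, segs))[0]
                for j in targets:
                    w = rule.weight
                    if rule.noise_sd > 0:
                        w = max(0.0, w * (1.0 + rule.noise_sd * rng.standard_normal()))
                    gi, gj = pre_start + i, post_start + int(j)
                    conns.append(
                        Connection(gi, gj, syn_kind[rule.syn], w, delay(gi, gj))
                    )
    return conns


def _muscle_synapses(model_populations, sheet, n_neurons, n_somites, cv):
    """One glutamatergic MN -> muscle synapse per somite per side (delay 0)."""
    w = sheet["chem_weights"]["MN_Muscle"]
    conns = []
    start = 0
    for p in model_populations:
        if p.kind == "MN":
            s = 0 if p.side == "left" else 1
            for i in range(p.count):
                post = n_neurons + s * n_somites + i
                conns.append(Connection(start + i, post, NMJ, w, 0.0))
        start += p.count
    return conns


# ---------------------------------------------------------------------------
# model factories


def _finish(name, sheet, populations, gap_rules, chem_rules, n_somites, rng, sigma_l,
            factory, factory_kwargs) -> CircuitModel:
    cv = sheet["cv"]
    conns = _realize_connections(
        populations,
        gap_rules,
        chem_rules,
        n_somites=n_somites,
        cv=cv,
        e_glut_chain_segments=0,
        rng=rng,
        sigma_l=sigma_l,
    )
    n_neurons = sum(p.count for p in populations)
    msyn = _muscle_synapses(populations, sheet, n_neurons, n_somites, cv)
    syn = sheet["synapse"]
    return CircuitModel(
        name=name,
        populations=populations,
        connections=conns,
        muscle_synapses=msyn,
        n_somites=n_somites,
        somite_length=sheet["somite_length"],
        cv=cv,
        dt=sheet["dt"],
        e_glut=syn["e_glut"],
        e_gly=syn["e_gly"],
        tau_r=syn["tau_r"],
        tau_f=syn["tau_f"],
        v_thr=syn["v_thr"],
        muscle_R=sheet["muscle"]["R"],
        muscle_C=sheet["muscle"]["C"],
        mn_muscle_weight=sheet["chem_weights"]["MN_Muscle"],
        body=dict(sheet["body"]),
        sheet=sheet,
        factory=factory,
        factory_kwargs=factory_kwargs,
    )


def _populations_from_sheet(sheet, model_variant, n_somites) -> list[PopulationSpec]:
    pops = []
    for side in ("left", "right"):
        for kind, spec in sheet["populations"].items():
            count = spec["count"]
            if kind != "IC" and count == sheet["n_somites"]:
                count = n_somites  # chain populations track body size
            p = PopulationSpec(
                kind=kind,
                side=side,
                count=count,
                params=IzhikevichParams(**spec["izhikevich"]),
                x=spec["position"]["offset"]
                + spec["position"]["spacing"] * np.arange(count, dtype=float),
                y=np.full(count, 1.0 if side == "right" else -1.0),
                drive=float(spec["drive"]["left" if side == "left" else "right"]),
                drive_onset=float(
                    spec["drive"].get("right_onset", spec["drive"].get("onset", 0.0))
                    if side == "right"
                    else spec["drive"].get("onset", 0.0)
                ),
                first_segment=2 if kind == "V1" else 1,
            )
            pops.append(p)
    return pops


def build_single_coiling(
    n_somites: int = 10,
    overrides: dict | None = None,
    rng: np.random.Generator | int | None = None,
    sigma_l: float = 0.0,
) -> CircuitModel:
    """The 10-somite (or 30-somite) single coiling model."""
    if n_somites not in (10, 30):
        raise ValueError("single coiling model supports 10 or 30 somites")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sheet = _apply_overrides(load_params("single_coiling"), overrides)
    pops = _populations_from_sheet(sheet, "single_coiling", n_somites)
    gw = sheet["gap_weights"]
    ext = sheet["gap_rules"]["neighbor_extent"]
    block = sheet["gap_rules"]["ic_block"] if n_somites == 10 else n_somites
    gap_rules = [
        GapRule("IC", "IC", gw["IC_IC"], "kernel"),
        GapRule("IC", "MN", gw["IC_MN"], "block", block),
        GapRule("IC", "V0d", gw["IC_V0d"], "block", block),
        GapRule("MN", "MN", gw["MN_MN"], "neighbor", ext),
        GapRule("V0d", "V0d", gw["V0d_V0d"], "neighbor", ext),
        GapRule("MN", "V0d", gw["MN_V0d"], "neighbor", ext),
    ]
    cw = sheet["chem_weights"]
    v0d_ext = sheet["chem_rules"]["v0d_extent"]
    chem_rules = [
        ChemRule("V0d", "MN", cw["V0d_MN"], "gly", True, v0d_ext, v0d_ext, True),
        ChemRule("V0d", "IC", cw["V0d_IC"], "gly", True, None, None, True),
    ]
    return _finish(
        "single_coiling", sheet, pops, gap_rules, chem_rules, n_somites, rng,
        sigma_l, "build_single_coiling",
        {"n_somites": n_somites, "overrides": overrides},
    )


def build_double_coiling(
    n_somites: int = 10,
    overrides: dict | None = None,
    rng: np.random.Generator | int | None = None,
    sigma_l: float = 0.0,
) -> CircuitModel:
    """The 10-somite (or 30-somite) double coiling model."""
    if n_somites not in (10, 30):
        raise ValueError("double coiling model supports 10 or 30 somites")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sheet = _apply_overrides(load_params("double_coiling"), overrides)
    pops = _populations_from_sheet(sheet, "double_coiling", n_somites)
    gw = sheet["gap_weights"]
    ext = sheet["gap_rules"]["neighbor_extent"]
    block = sheet["gap_rules"]["ic_block"] if n_somites == 10 else n_somites
    gap_rules = [
        GapRule("IC", "IC", gw["IC_IC"], "kernel"),
        GapRule("IC", "MN", gw["IC_MN"], "block", block),
        GapRule("IC", "V0d", gw["IC_V0d"], "block", block),
        GapRule("IC", "V0v", gw["IC_V0v"], "block", block),
        GapRule("IC", "V2a", gw["IC_V2a"],
                sheet["gap_rules"].get("ic_v2a_mode", "all"), block,
                reciprocal=bool(sheet["gap_rules"].get("ic_v2a_reciprocal", True))),
        GapRule("MN", "MN", gw["MN_MN"], "neighbor", ext),
        GapRule("V0d", "V0d", gw["V0d_V0d"], "neighbor", ext),
        GapRule("MN", "V0d", gw["MN_V0d"], "neighbor", ext),
        GapRule("V0v", "V0v", gw["V0v_V0v"], "neighbor", ext),
        GapRule("MN", "V0v", gw["MN_V0v"], "neighbor", ext),
        GapRule("V0v", "V0d", gw["V0v_V0d"], "neighbor", ext),
        GapRule("MN", "V2a", gw["MN_V2a"], "neighbor", ext),
        GapRule("V2a", "V2a", gw["V2a_V2a"], "neighbor", ext),
    ]
    cw = sheet["chem_weights"]
    v0d_ext = sheet["chem_rules"]["v0d_extent"]
    v2a_ext = sheet["chem_rules"]["v2a_v0v_extent"]
    chem_rules = [
        ChemRule("V0d", "MN", cw["V0d_MN"], "gly", True, v0d_ext, v0d_ext, True),
        ChemRule("V0d", "IC", cw["V0d_IC"], "gly", True, None, None, True),
        ChemRule("V0d", "V2a", cw["V0d_V2a"], "gly", True, v0d_ext, v0d_ext, True),
        ChemRule("V0v", "IC", cw["V0v_IC"], "glut", True, None, None, True),
        ChemRule("V2a", "V0v", cw["V2a_V0v"], "glut", False, v2a_ext, v2a_ext, True),
    ]
    return _finish(
        "double_coiling", sheet, pops, gap_rules, chem_rules, n_somites, rng,
        sigma_l, "build_double_coiling",
        {"n_somites": n_somites, "overrides": overrides},
    )


def build_beat_and_glide(
    variant: str = "base",
    n_somites: int = 15,
    overrides: dict | None = None,
    rng: np.random.Generator | int | None = None,
    sigma_l: float = 0.0,
) -> CircuitModel:
    """The beat-and-glide swimming model (base, bursting_v2a, or all_tonic)."""
    names = {
        "base": "beat_glide_base",
        "bursting_v2a": "beat_glide_bursting_v2a",
        "all_tonic": "beat_glide_all_tonic",
    }
    if variant not in names:
        raise ValueError(f"unknown beat-and-glide variant {variant!r}")
    if n_somites not in (10, 15, 30):
        raise ValueError("beat-and-glide model supports 10, 15, or 30 somites")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sheet = _apply_overrides(load_params(names[variant]), overrides)
    pops = _populations_from_sheet(sheet, names[variant], n_somites)
    gw = sheet["gap_weights"]
    ext = sheet["gap_rules"]["neighbor_extent"]
    gap_rules = [
        GapRule("MN", "MN", gw["MN_MN"], "neighbor", ext),
        GapRule("dI6", "MN", gw["dI6_MN"], "neighbor", ext),
        GapRule("dI6", "dI6", gw["dI6_dI6"], "neighbor", ext),
        GapRule("V0v", "MN", gw["V0v_MN"], "neighbor", ext),
        GapRule("V0v", "V0v", gw["V0v_V0v"], "neighbor", ext),
        GapRule("V2a", "MN", gw["V2a_MN"], "neighbor", ext),
        GapRule("V2a", "V2a", gw["V2a_V2a"], "neighbor", ext),
    ]
    cw = sheet["chem_weights"]
    cr = sheet["chem_rules"]
    noise = cr["di6_noise_sd"]
    chem_rules = [
        ChemRule("dI6", "MN", cw["dI6_MN"], "gly", True, cr["dI6_asc"], cr["dI6_desc"]),
        ChemRule("dI6", "dI6", cw["dI6_dI6"], "gly", True, cr["dI6_asc"],
                 cr["dI6_desc"], noise_sd=noise),
        ChemRule("dI6", "V2a", cw["dI6_V2a"], "gly", True, cr["dI6_asc"], cr["dI6_desc"]),
        ChemRule("V0v", "V2a", cw["V0v_V2a"], "glut", True, cr["v0v_asc"], cr["v0v_desc"]),
        # "segmental and descending/ascending": V2a and V1 also contact their own
        # segment; V2a->V2a is caudal-only
        ChemRule("V2a", "MN", cw["V2a_MN"], "glut", False, cr["v2a_asc"],
                 cr["v2a_desc"], True),
        ChemRule("V2a", "V0v", cw["V2a_V0v"], "glut", False, cr["v2a_asc"],
                 cr["v2a_desc"], True),
        ChemRule("V2a", "dI6", cw["V2a_dI6"], "glut", False, 0, cr["v2a_desc"], True),
        ChemRule("V2a", "V2a", cw["V2a_V2a"], "glut", False, 0, cr["v2a_desc"]),
        ChemRule("V2a", "V1", cw["V2a_V1"], "glut", False, 0, cr["v2a_desc"], True),
        ChemRule("V1", "MN", cw["V1_MN"], "gly", False, cr["v1_asc"], 0, True),
        ChemRule("V1", "dI6", cw["V1_dI6"], "gly", False, cr["v1_asc"], 0, True),
        ChemRule("V1", "V0v", cw["V1_V0v"], "gly", False, cr["v1_asc"], 0, True),
        ChemRule("V1", "V2a", cw["V1_V2a"], "gly", False, cr["v1_asc"], 0, True),
    ]
    return _finish(
        names[variant], sheet, pops, gap_rules, chem_rules, n_somites, rng,
        sigma_l, "build_beat_and_glide",
        {"variant": variant, "n_somites": n_somites, "overrides": overrides},
    )


MODEL_FACTORIES = {
    "single_coiling": build_single_coiling,
    "double_coiling": build_double_coiling,
    "beat_glide_base": lambda **kw: build_beat_and_glide("base", **kw),
    "beat_glide_bursting_v2a": lambda **kw: build_beat_and_glide("bursting_v2a", **kw),
    "beat_glide_all_tonic": lambda **kw: build_beat_and_glide("all_tonic", **kw),
}


def build_model(name: str, **kwargs) -> CircuitModel:
    """Build a model by registry name (see :data:`MODEL_FACTORIES`)."""
    try:
        factory = MODEL_FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; known: {sorted(MODEL_FACTORIES)}"
        ) from None
    return factory(**kwargs)


def export_connectome(model: CircuitModel) -> pd.DataFrame:
    """Edge list (pre, post, kind, weight, delay) for inspection or CSV export."""
    rows = [
        (c.pre, c.post, c.kind, c.weight, c.delay)
        for c in model.connections + model.muscle_synapses
    ]
    return pd.DataFrame(rows, columns=["pre", "post", "kind", "weight", "delay"])
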