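"""Domain types, clinical-table fixtures, and synthetic coronary tree generation.

The package operates on reduced-order coronary trees: rooted binary trees of
cylindrical vessel segments with optional focal stenoses and an optional
pressure guidewire running from the ostium past a lesion.  Real anatomies are
CCTA-derived and not public; the generator below emulates their salient
features (Murray-consistent bifurcation radii, realistic length-to-radius
ratios, stenoses spanning the clinical severity spectrum) so that the full
prediction pipeline can be exercised and its paired wire-absent /
wire-included behaviour studied.
"""

from __future__ import annotations

import copy
import importlib.resources
import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

DEFAULT_WIRE_DIAMETER_CM = 0.036  # clinical pressure guidewire (0.014")
DEFAULT_CYCLE_DURATION_S = 0.8
DEFAULT_PULSE_PRESSURE_MMHG = 40.0

# Invasive FFR severity classes, most severe first.  Boundary convention:
# class 1 takes its upper edge, class 3 takes its lower edge and class 4 its
# lower edge; this is the unique assignment putting six of the 24 packaged
# invasive measurements in each class.
FFR_CLASS_EDGES = (0.38, 0.52, 0.72, 0.84, 1.0)


class WireFitError(ValueError):
    """Raised when the guidewire does not fit through a lumen on its path."""


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """Per-patient clinical parameters.

    Parameters
    ----------
    map_mmHg : mean aortic pressure, mmHg.
    co_l_min : cardiac output, L/min.
    dominance : 'right' or 'left' coronary arterial dominance.
    cycle_duration_s : cardiac cycle duration; not part of the printed
        clinical table, defaults to 0.8 s.
    pulse_pressure_mmHg : aortic pulse pressure; defaults to 40 mmHg.
    """

    patient_id: int
    map_mmHg: float
    co_l_min: float
    dominance: str
    cycle_duration_s: float = DEFAULT_CYCLE_DURATION_S
    pulse_pressure_mmHg: float = DEFAULT_PULSE_PRESSURE_MMHG

    def __post_init__(self) -> None:
        if self.map_mmHg <= 0 or self.co_l_min <= 0:
            raise ValueError("MAP and CO must be positive")
        if self.cycle_duration_s <= 0 or self.pulse_pressure_mmHg <= 0:
            raise ValueError("cycle duration and pulse pressure must be positive")
        if self.dominance not in ("right", "left"):
            raise ValueError(f"dominance must be 'right' or 'left', got {self.dominance!r}")


@dataclass(frozen=True)
class LesionRecord:
    """One invasively measured lesion: location label and invasive FFR."""

    ffr_id: int
    patient_id: int
    location: str
    ffr_invasive: float

    def __post_init__(self) -> None:
        if not 0 < self.ffr_invasive <= 1:
            raise ValueError("invasive FFR must lie in (0, 1]")


def _fixture_path(name: str):
    return importlib.resources.files("coroflow.fixtures").joinpath(name)


def load_patient_fixtures() -> list[PatientRecord]:
    """Load the packaged 18-patient clinical table (MAP, CO, dominance)."""
    path = _fixture_path("patients.csv")
    try:
        df = pd.read_csv(path)
        return [
            PatientRecord(int(r.patient_id), float(r.map_mmHg), float(r.co_l_min), str(r.dominance))
            for r in df.itertuples()
        ]
    except (OSError, KeyError, ValueError) as exc:
        raise RuntimeError(f"corrupted patient fixture file {path}: {exc}") from exc


def load_lesion_fixtures() -> list[LesionRecord]:
    """Load the packaged 24-lesion invasive-FFR table."""
    path = _fixture_path("lesions.csv")
    try:
        df = pd.read_csv(path)
        records = [
            LesionRecord(int(r.ffr_id), int(r.patient_id), str(r.location), float(r.ffr_invasive))
            for r in df.itertuples()
        ]
    except (OSError, KeyError, ValueError) as exc:
        raise RuntimeError(f"corrupted lesion fixture file {path}: {exc}") from exc
    patient_ids = {p.patient_id for p in load_patient_fixtures()}
    for rec in records:
        if rec.patient_id not in patient_ids:
            raise RuntimeError(f"lesion {rec.ffr_id} references unknown patient {rec.patient_id}")
    return records


# ---------------------------------------------------------------------------
# Tree geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StenosisSpec:
    """Focal stenosis: fractional *area* reduction (1 - A_s/A_0), throat
    length in cm, and fractional position along the host segment."""

    degree: float
    stenosis_length_cm: float
    position: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.degree < 1:
            raise ValueError("stenosis degree must lie in [0, 1); total occlusion unsupported")
        if self.stenosis_length_cm <= 0:
            raise ValueError("stenosis length must be positive")
        if not 0 <= self.position <= 1:
            raise ValueError("stenosis position must lie in [0, 1]")


@dataclass(frozen=True)
class WireSpec:
    """Pressure guidewire: diameter (cm) and ordered segment path from the
    tree inlet to the measurement segment."""

    path: tuple[int, ...]
    diameter_cm: float = DEFAULT_WIRE_DIAMETER_CM

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0:
            raise ValueError("wire diameter must be positive")


@dataclass
class VesselSegment:
    segment_id: int
    parent_id: Optional[int]
    length_cm: float
    radius_cm: float
    stenosis: Optional[StenosisSpec] = None
    wire_present: bool = False

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.radius_cm <= 0:
            raise ValueError("segment length and radius must be positive")

    @property
    def throat_radius_cm(self) -> float:
        """Lumen radius at the narrowest point (stenotic throat if present)."""
        if self.stenosis is None:
            return self.radius_cm
        return self.radius_cm * math.sqrt(1.0 - self.stenosis.degree)


@dataclass
class Measurement:
    """Location of the distal pressure recording: the lesion segment and the
    nominal distance distal to it where p_d is taken."""

    lesion_segment_id: int
    distal_offset_cm: float = 2.5
    segment_id: Optional[int] = None  # resolved node (distal end of this segment)


@dataclass
class CoronaryTree:
    """Rooted tree of vessel segments; the root's proximal node is the inlet
    (coronary ostium) where aortic pressure is imposed."""

    segments: dict[int, VesselSegment]
    inlet_id: int
    measurement: Optional[Measurement] = None
    wire: Optional[WireSpec] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- topology ----------------------------------------------------------
    def validate(self) -> None:
        roots = [s for s in self.segments.values() if s.parent_id is None]
        if len(roots) != 1 or roots[0].segment_id != self.inlet_id:
            raise ValueError("tree must have exactly one root matching inlet_id")
        seen: set[int] = set()
        for seg in self.segments.values():
            if seg.parent_id is not None and seg.parent_id not in self.segments:
                raise ValueError(f"segment {seg.segment_id} has unknown parent {seg.parent_id}")
            sid, hops = seg.segment_id, 0
            while sid is not None:
                hops += 1
                if hops > len(self.segments):
                    raise ValueError("cycle detected in segment graph")
                sid = self.segments[sid].parent_id
            seen.add(seg.segment_id)
        if len(seen) != len(self.segments):
            raise ValueError("duplicate segment ids")

    def children(self, segment_id: int) -> list[int]:
        return sorted(
            s.segment_id for s in self.segments.values() if s.parent_id == segment_id
        )

    @property
    def outlet_ids(self) -> list[int]:
        """Terminal segments, sorted by id (the N model outlets)."""
        return sorted(s.segment_id for s in self.segments.values() if not self.children(s.segment_id))

    def path_to(self, segment_id: int) -> list[int]:
        """Segment ids from the inlet down to (and including) segment_id."""
        path = []
        sid: Optional[int] = segment_id
        while sid is not None:
            path.append(sid)
            sid = self.segments[sid].parent_id
        return path[::-1]

    def copy(self) -> "CoronaryTree":
        return copy.deepcopy(self)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "inlet_id": self.inlet_id,
            "segments": [
                {
                    "segment_id": s.segment_id,
                    "parent_id": s.parent_id,
                    "length_cm": s.length_cm,
                    "radius_cm": s.radius_cm,
                    "wire_present": s.wire_present,
                    "stenosis": None
                    if s.stenosis is None
                    else {
                        "degree": s.stenosis.degree,
                        "stenosis_length_cm": s.stenosis.stenosis_length_cm,
                        "position": s.stenosis.position,
                    },
                }
                for s in sorted(self.segments.values(), key=lambda s: s.segment_id)
            ],
        }
        if self.measurement is not None:
            d["measurement"] = {
                "lesion_segment_id": self.measurement.lesion_segment_id,
                "distal_offset_cm": self.measurement.distal_offset_cm,
                "segment_id": self.measurement.segment_id,
            }
        if self.wire is not None:
            d["wire"] = {"path": list(self.wire.path), "wire_diameter_cm": self.wire.diameter_cm}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CoronaryTree":
        segments = {
            s["segment_id"]: VesselSegment(
                segment_id=s["segment_id"],
                parent_id=s["parent_id"],
                length_cm=s["length_cm"],
                radius_cm=s["radius_cm"],
                wire_present=s.get("wire_present", False),
                stenosis=None
                if s.get("stenosis") is None
                else StenosisSpec(
                    degree=s["stenosis"]["degree"],
                    stenosis_length_cm=s["stenosis"]["stenosis_length_cm"],
                    position=s["stenosis"].get("position", 0.5),
                ),
            )
            for s in d["segments"]
        }
        measurement = None
        if d.get("measurement") is not None:
            m = d["measurement"]
            measurement = Measurement(m["lesion_segment_id"], m["distal_offset_cm"], m.get("segment_id"))
        wire = None
        if d.get("wire") is not None:
            wire = WireSpec(tuple(d["wire"]["path"]), d["wire"]["wire_diameter_cm"])
        return cls(segments=segments, inlet_id=d["inlet_id"], measurement=measurement, wire=wire)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "CoronaryTree":
        return cls.from_dict(json.loads(text))


def generate_tree(
    n_generations: int,
    root_radius_cm: float = 0.15,
    seed: int | np.random.Generator = 0,
    *,
    root_length_cm: Optional[float] = None,
    length_to_radius: tuple[float, float] = (8.0, 12.0),
    flow_asymmetry: tuple[float, float] = (0.40, 0.50),
    murray_exponent: float = 3.0,
) -> CoronaryTree:
    """Generate a binary coronary tree with Murray-consistent radii.

    At each bifurcation the parent radius r_p is split so that
    r_left^m + r_right^m = r_p^m with m the Murray exponent (default 3); the
    flow share of the smaller daughter is drawn uniformly from
    ``flow_asymmetry``.  Segment lengths are radius-proportional with a
    length-to-radius ratio drawn uniformly from ``length_to_radius``
    (epicardial coronaries typically run ~8-12 lumen radii between branch
    points).  Deterministic for a fixed seed.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if root_radius_cm <= 0:
        raise ValueError("root_radius_cm must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    segments: dict[int, VesselSegment] = {}
    next_id = 0

    def make_segment(parent_id: Optional[int], radius: float, length: float) -> int:
        nonlocal next_id
        sid = next_id
        next_id += 1
        segments[sid] = VesselSegment(sid, parent_id, length, radius)
        return sid

    root_len = root_length_cm if root_length_cm is not None else root_radius_cm * rng.uniform(*length_to_radius)
    frontier = [(make_segment(None, root_radius_cm, root_len), root_radius_cm, 1)]
    while frontier:
        parent_id, r_p, gen = frontier.pop(0)
        if gen >= n_generations:
            continue
        gamma = rng.uniform(*flow_asymmetry)  # flow share of the minor daughter
        r_minor = r_p * gamma ** (1.0 / murray_exponent)
        r_major = r_p * (1.0 - gamma) ** (1.0 / murray_exponent)
        for r in (r_major, r_minor):
            length = r * rng.uniform(*length_to_radius)
            cid = make_segment(parent_id, r, length)
            frontier.append((cid, r, gen + 1))
    return CoronaryTree(segments=segments, inlet_id=0)


def resolve_measurement(tree: CoronaryTree, lesion_segment_id: int, distal_offset_cm: float = 2.5) -> Measurement:
    """Place the p_d recording point ~``distal_offset_cm`` beyond the lesion.

    Walks distally from the lesion along the largest-radius daughter chain,
    accumulating segment length, and records the segment whose distal node
    first reaches the offset (clipped to the branch end), mimicking the
    clinical 2-3 cm distal sensor position.
    """
    if lesion_segment_id not in tree.segments:
        raise KeyError(f"no segment {lesion_segment_id} in tree")
    sid = lesion_segment_id
    travelled = 0.0
    while travelled < distal_offset_cm:
        kids = tree.children(sid)
        if not kids:
            break
        sid = max(kids, key=lambda k: tree.segments[k].radius_cm)
        travelled += tree.segments[sid].length_cm
    return Measurement(lesion_segment_id, distal_offset_cm, segment_id=sid)


def add_stenosis(
    tree: CoronaryTree,
    segment_id: int,
    degree: float,
    stenosis_length_cm: Optional[float] = None,
    position: float = 0.5,
    distal_offset_cm: float = 2.5,
) -> CoronaryTree:
    """Return a copy of ``tree`` with a stenosis on ``segment_id``.

    Also resolves the distal measurement point for the lesion if the tree has
    none yet.  The input tree is not modified.
    """
    if segment_id not in tree.segments:
        raise KeyError(f"no segment {segment_id} in tree")
    seg = tree.segments[segment_id]
    if stenosis_length_cm is None:
        stenosis_length_cm = 0.5 * seg.length_cm
    if stenosis_length_cm > seg.length_cm:
        raise ValueError("stenosis longer than host segment")
    spec = StenosisSpec(degree=degree, stenosis_length_cm=stenosis_length_cm, position=position)
    out = tree.copy()
    out.segments[segment_id].stenosis = spec
    if out.measurement is None:
        out.measurement = resolve_measurement(out, segment_id, distal_offset_cm)
    return out


def default_wire_path(tree: CoronaryTree, path_mode: str = "ostium_to_sensor") -> tuple[int, ...]:
    """Guidewire course ending at the p_d measurement segment.

    'ostium_to_sensor' runs from the tree inlet (the clinical wire enters at
    the ostium and its sensor sits distal to the lesion); 'stenotic_branch'
    covers only the stenotic branch, from the lesion segment to the
    measurement segment.
    """
    if tree.measurement is None or tree.measurement.segment_id is None:
        raise ValueError("tree has no resolved measurement point; add a stenosis first")
    full = tree.path_to(tree.measurement.segment_id)
    if path_mode == "ostium_to_sensor":
        return tuple(full)
    if path_mode == "stenotic_branch":
        return tuple(full[full.index(tree.measurement.lesion_segment_id):])
    raise ValueError(f"unknown wire path mode {path_mode!r}")


def insert_guidewire(tree: CoronaryTree, wire: Optional[WireSpec] = None) -> CoronaryTree:
    """Return a copy of ``tree`` with the guidewire inserted along ``wire.path``.

    Every segment on the path becomes annular: the effective lumen is the gap
    between the wall (stenotic throat included) and the wire.  Raises
    :class:`WireFitError` if the wire is thicker than any lumen on the path.
    """
    if wire is None:
        wire = WireSpec(path=default_wire_path(tree))
    out = tree.copy()
    if not wire.path:
        return out
    r_wire = wire.diameter_cm / 2.0
    for sid in wire.path:
        if sid not in out.segments:
            raise KeyError(f"wire path references unknown segment {sid}")
        throat = out.segments[sid].throat_radius_cm
        if r_wire >= throat:
            raise WireFitError(
                f"wire does not fit: radius {r_wire:.4f} cm >= lumen radius "
                f"{throat:.4f} cm on segment {sid}"
            )
    for sid in wire.path:
        out.segments[sid].wire_present = True
    out.wire = wire
    return out


# ---------------------------------------------------------------------------
# Calibrated cohorts
# ---------------------------------------------------------------------------

def classify_ffr(value: float) -> int:
    """Map an FFR value to its severity class (1 = most severe .. 4 = mildest)."""
    if not 0 < value <= 1:
        raise ValueError(f"FFR must lie in (0, 1], got {value}")
    if value <= FFR_CLASS_EDGES[1]:
        return 1
    if value < FFR_CLASS_EDGES[2]:
        return 2
    if value < FFR_CLASS_EDGES[3]:
        return 3
    return 4


def ffr_class_interval(ffr_class: int) -> tuple[float, float]:
    if ffr_class not in (1, 2, 3, 4):
        raise ValueError("FFR class must be 1..4")
    return FFR_CLASS_EDGES[ffr_class - 1], FFR_CLASS_EDGES[ffr_class]


@dataclass
class CohortLesion:
    """One synthetic lesion: patient parameters, calibrated stenotic tree
    (wire-absent), its severity class, and the paired invasive measurement."""

    lesion_id: int
    ffr_id: int
    patient: PatientRecord
    tree: CoronaryTree
    ffr_class: int
    target_ffr: float
    calibrated_ffr: float
    stenosis_degree: float
    ffr_invasive: float


def _calibrate_degree(
    tree: CoronaryTree,
    lesion_segment: int,
    patient: PatientRecord,
    target_ffr: float,
    config,
    tol: float = 0.005,
    max_iter: int = 60,
) -> tuple[CoronaryTree, float, float, float]:
    """Bisect the stenosis degree so the wire-absent steady hyperemic FFR
    hits ``target_ffr`` (monotone decreasing FFR-vs-degree relation).
    Returns (tree, degree, achieved FFR, effective target)."""
    from .study import predict_lesion  # deferred: cohort calibration runs the pipeline

    def ffr_at(degree: float) -> tuple[float, CoronaryTree]:
        t = add_stenosis(tree, lesion_segment, degree,
                         distal_offset_cm=config.measurement.distal_offset_cm)
        try:
            res = predict_lesion(t, patient, config, wire=False, mode="steady")
        except ValueError:
            # resting outlet pressure at/below venous: the probe degree is
            # beyond the physiologic range, i.e. FFR far below any target
            return -math.inf, t
        return res.ffr, t

    lo, hi = 0.0, 0.90
    f_lo, _ = ffr_at(lo)
    # the healthy tree caps achievable FFR below 1 (viscous losses); clip
    # targets above the ceiling to just under it — still inside class 4
    if target_ffr > f_lo - 0.005:
        target_ffr = f_lo - 0.005
    f_hi, _ = ffr_at(hi)
    while f_hi > target_ffr and hi < 0.985:
        hi = min(0.985, hi + 0.04)
        f_hi, _ = ffr_at(hi)
    if f_lo < target_ffr or f_hi > target_ffr:
        raise RuntimeError(
            f"cannot bracket target FFR {target_ffr:.3f}: FFR({lo})={f_lo:.3f}, FFR({hi})={f_hi:.3f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid, t_mid = ffr_at(mid)
        if abs(f_mid - target_ffr) <= tol:
            return t_mid, mid, f_mid, target_ffr
        if f_mid > target_ffr:
            lo = mid
        else:
            hi = mid
    t_mid = add_stenosis(tree, lesion_segment, 0.5 * (lo + hi),
                         distal_offset_cm=config.measurement.distal_offset_cm)
    return t_mid, 0.5 * (lo + hi), f_mid, target_ffr


def generate_cohort(n_per_class: int = 6, seed: int = 0, config=None) -> list[CohortLesion]:
    """Generate a calibrated synthetic cohort spanning the four FFR classes.

    For each class, trees are generated and their stenosis degree is bisected
    until the wire-absent predicted FFR (steady hyperemic mode) lands on a
    target drawn from the interior of the class interval.  Each synthetic
    lesion is paired with a packaged invasive measurement of the same class
    (cycling through them) so diagnostic statistics can be computed.
    Deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if config is None:
        from .config import PipelineConfig

        config = PipelineConfig()
    rng = np.random.default_rng(seed)
    patients = load_patient_fixtures()
    lesions_by_class: dict[int, list[LesionRecord]] = {c: [] for c in (1, 2, 3, 4)}
    for rec in load_lesion_fixtures():
        lesions_by_class[classify_ffr(rec.ffr_invasive)].append(rec)
    patient_map = {p.patient_id: p for p in patients}

    margin = 0.03
    cohort: list[CohortLesion] = []
    lesion_id = 0
    for ffr_class in (1, 2, 3, 4):
        lo, hi = ffr_class_interval(ffr_class)
        fixtures = lesions_by_class[ffr_class]
        for i in range(n_per_class):
            fixture = fixtures[i % len(fixtures)]
            patient = patient_map[fixture.patient_id]
            target = rng.uniform(lo + margin, hi - margin)
            tree = generate_tree(
                config.tree.n_generations,
                config.tree.root_radius_cm,
                seed=rng,
            )
            # lesion on the major (largest-radius) daughter of the root, a
            # typical proximal/mid epicardial location; root itself if the
            # tree has a single segment
            kids = tree.children(tree.inlet_id)
            lesion_segment = max(kids, key=lambda k: tree.segments[k].radius_cm) if kids else tree.inlet_id
            try:
                calibrated_tree, degree, achieved, target = _calibrate_degree(
                    tree, lesion_segment, patient, target, config
                )
            except RuntimeError as exc:
                raise RuntimeError(
                    f"cohort calibration failed for class {ffr_class}, seed {seed}: {exc}"
                ) from exc
            lesion_id += 1
            cohort.append(
                CohortLesion(
                    lesion_id=lesion_id,
                    ffr_id=fixture.ffr_id,
                    patient=patient,
                    tree=calibrated_tree,
                    ffr_class=ffr_class,
                    target_ffr=target,
                    calibrated_ffr=achieved,
                    stenosis_degree=degree,
                    ffr_invasive=fixture.ffr_invasive,
                )
            )
    return cohort
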