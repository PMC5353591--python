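"""Synthetic inputs: digital thorax phantoms and simulated patient cohorts.

Nothing in this pipeline requires downloaded data. Three generators cover the
inputs the analysis needs:

* ``generate_phantom`` — a geometric thorax: two ellipsoidal lungs, one or
  more rectangular or Gaussian dose fields with peaks in the clinical 60–66 Gy
  prescription range, and perfusion/ventilation activity maps with
  multiplicative lognormal noise and optional perfusion- or ventilation-only
  defect regions (the V/Q mismatch pattern: a region with almost absent
  ventilation but preserved perfusion, or vice versa).
* ``figure1_fixture`` — a deterministic two-patient worked example built by
  exact voxel allocation: both cases have anatomical V20 = 25%, while the
  functional V20s are 35%/33% (Q/V) for the toxicity case and 20%/22% for the
  non-toxicity case. The construction is combinatorial, so the pipeline
  reproduces those percentages exactly rather than approximately.
* ``simulate_cohort`` / ``table1_fixture`` — a Gaussian-copula cohort
  simulator: a latent toxicity propensity z ~ N(0,1) drives each metric
  through a planted latent correlation rho per metric family (CT / Q / V),
  and the RILT event probability is logistic in z. The achieved metric–latent
  rank correlation targets (6/pi) arcsin(rho/2).

All generators are pure functions of (spec, seed) and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, ndtr

from .cohort import COVARIATE_LEVELS, PatientRecord
from .dosimetry import MetricRecord
from .grid import BinaryMask, ImageGrid
from .segmentation import FunctionalMask


# --------------------------------------------------------------------------
# Phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in patient coordinates (mm)."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def contains(self, coords: list[np.ndarray]) -> np.ndarray:
        acc = 0.0
        for ax in range(3):
            shape = [1, 1, 1]
            shape[ax] = -1
            c = coords[ax].reshape(shape)
            acc = acc + ((c - self.center_mm[ax]) / self.radii_mm[ax]) ** 2
        return acc <= 1.0


@dataclass(frozen=True)
class BeamField:
    """One dose field: ``box`` (uniform inside) or ``gaussian`` peak."""

    kind: str = "gaussian"
    center_mm: tuple[float, float, float] = (80.0, 80.0, 64.0)
    size_mm: tuple[float, float, float] = (40.0, 40.0, 50.0)
    peak_gy: float = 63.0

    def __post_init__(self):
        if self.kind not in ("gaussian", "box"):
            raise ValueError(f"field kind must be 'gaussian' or 'box', got {self.kind!r}")
        if self.peak_gy <= 0:
            raise ValueError("peak dose must be positive")

    def dose(self, coords: list[np.ndarray]) -> np.ndarray:
        if self.kind == "box":
            inside = np.ones((1, 1, 1), dtype=bool)
            for ax in range(3):
                shape = [1, 1, 1]
                shape[ax] = -1
                c = coords[ax].reshape(shape)
                inside = inside & (np.abs(c - self.center_mm[ax]) <= self.size_mm[ax] / 2.0)
            return self.peak_gy * inside.astype(float)
        acc = 0.0
        for ax in range(3):
            shape = [1, 1, 1]
            shape[ax] = -1
            c = coords[ax].reshape(shape)
            acc = acc + ((c - self.center_mm[ax]) / self.size_mm[ax]) ** 2
        return self.peak_gy * np.exp(-0.5 * acc)


@dataclass(frozen=True)
class DefectSpec:
    """A functional defect: residual activity fraction inside an ellipsoid."""

    modality: str  # "perfusion", "ventilation" or "both"
    region: Ellipsoid
    residual: float = 0.05

    def __post_init__(self):
        if self.modality not in ("perfusion", "ventilation", "both"):
            raise ValueError(f"defect modality {self.modality!r} invalid")
        if not 0.0 <= self.residual < 1.0:
            raise ValueError("residual activity fraction must be in [0, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, dose model and activity model for one synthetic patient.

    Defaults: 40 x 40 x 32 voxels at 4 mm isotropic (grid resolutions are not
    dictated by the underlying study; these are documented working choices),
    two ellipsoidal lungs, one 63 Gy Gaussian field centered between them,
    uniform baseline activity of 100 counts with 15% lognormal noise.
    """

    shape: tuple[int, int, int] = (40, 40, 32)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lungs: tuple[Ellipsoid, ...] = (
        Ellipsoid(center_mm=(52.0, 78.0, 62.0), radii_mm=(26.0, 40.0, 50.0)),
        Ellipsoid(center_mm=(106.0, 78.0, 62.0), radii_mm=(26.0, 40.0, 50.0)),
    )
    dose_fields: tuple[BeamField, ...] = (BeamField(),)
    baseline_counts: float = 100.0
    noise_sigma: float = 0.15
    defects: tuple[DefectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if min(self.shape) < 1 or min(self.spacing_mm) <= 0:
            raise ValueError("phantom grid must have positive shape and spacing")
        if self.baseline_counts <= 0:
            raise ValueError("baseline activity must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class PhantomBundle:
    """Aligned dose, perfusion/ventilation activity, and lung mask."""

    dose: ImageGrid
    q_activity: ImageGrid
    v_activity: ImageGrid
    lung: BinaryMask


def _axis_coords(spec: PhantomSpec) -> list[np.ndarray]:
    return [
        spec.origin_mm[ax] + spec.spacing_mm[ax] * np.arange(spec.shape[ax])
        for ax in range(3)
    ]


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build one phantom; deterministic given ``spec.seed``."""
    coords = _axis_coords(spec)
    lung = np.zeros(spec.shape, dtype=bool)
    for ell in spec.lungs:
        lung |= ell.contains(coords)
    if not lung.any():
        raise ValueError("lung ellipsoids contain no voxels on this grid")

    dose = np.zeros(spec.shape, dtype=float)
    for fld in spec.dose_fields:
        dose += fld.dose(coords)

    rng = np.random.default_rng(spec.seed)
    activities = {}
    for modality in ("perfusion", "ventilation"):
        if spec.noise_sigma > 0:
            # mean-preserving lognormal: E[exp(s N - s^2/2)] = 1
            noise = np.exp(
                spec.noise_sigma * rng.standard_normal(spec.shape)
                - spec.noise_sigma**2 / 2.0
            )
        else:
            noise = np.ones(spec.shape)
        act = np.where(lung, spec.baseline_counts * noise, 0.0)
        activities[modality] = act
    for defect in spec.defects:
        region = defect.region.contains(coords)
        if not region.any():
            raise ValueError("defect region contains no voxels")
        if (region & ~lung).any():
            raise ValueError(
                f"{defect.modality} defect at {defect.region.center_mm} extends outside the lung"
            )
        targets = (
            ("perfusion", "ventilation") if defect.modality == "both" else (defect.modality,)
        )
        for modality in targets:
            act = activities[modality]
            activities[modality] = np.where(region, act * defect.residual, act)

    geom = dict(spacing=spec.spacing_mm, origin=spec.origin_mm)
    return PhantomBundle(
        dose=ImageGrid(dose, **geom),
        q_activity=ImageGrid(activities["perfusion"], **geom),
        v_activity=ImageGrid(activities["ventilation"], **geom),
        lung=BinaryMask(lung, **geom),
    )


# --------------------------------------------------------------------------
# Figure-1 worked-example fixture
# --------------------------------------------------------------------------

#: Exact voxel-allocation parameters for the two-case worked example.
#: (lung voxels, high-dose voxels, |Q|, |high ∩ Q|, |V|, |high ∩ V|)
FIGURE1_ALLOCATION = {
    # 700/2000 = 35%, 990/3000 = 33%; anatomical 2500/10000 = 25%
    "rilt_case": dict(n_lung=10_000, n_high=2500, n_q=2000, q_high=700, n_v=3000, v_high=990),
    # 400/2000 = 20%, 550/2500 = 22%
    "non_rilt_case": dict(n_lung=10_000, n_high=2500, n_q=2000, q_high=400, n_v=2500, v_high=550),
}

_FIG1_SHAPE = (27, 22, 22)           # 1-voxel air margin around a 25x20x20 lung block
_FIG1_BLOCK = (slice(1, 26), slice(1, 21), slice(1, 21))
_FIG1_SPACING = (3.0, 3.0, 3.0)
_FIG1_HIGH_GY = 25.0                 # >= 20 Gy: counts toward V20
_FIG1_LOW_GY = 5.0
_FIG1_ACT_IN = 1.0                   # two-level activity: 30% threshold
_FIG1_ACT_OUT = 0.1                  # recovers the intended mask exactly
_FIG1_LOW_OFFSET = 200               # V's low-dose allocation skips Q's first voxels


def _figure1_case(alloc: dict) -> PhantomBundle:
    lung = np.zeros(_FIG1_SHAPE, dtype=bool)
    lung[_FIG1_BLOCK] = True
    flat = np.flatnonzero(lung.reshape(-1))
    assert flat.size == alloc["n_lung"]
    high_idx = flat[: alloc["n_high"]]
    low_idx = flat[alloc["n_high"]:]

    dose = np.zeros(_FIG1_SHAPE)
    dose.reshape(-1)[high_idx] = _FIG1_HIGH_GY
    dose.reshape(-1)[low_idx] = _FIG1_LOW_GY

    def two_level_activity(n_total: int, n_high: int, low_offset: int) -> np.ndarray:
        members = np.concatenate(
            [high_idx[:n_high], low_idx[low_offset: low_offset + (n_total - n_high)]]
        )
        act = np.zeros(_FIG1_SHAPE)
        act.reshape(-1)[flat] = _FIG1_ACT_OUT
        act.reshape(-1)[members] = _FIG1_ACT_IN
        return act

    q_act = two_level_activity(alloc["n_q"], alloc["q_high"], 0)
    v_act = two_level_activity(alloc["n_v"], alloc["v_high"], _FIG1_LOW_OFFSET)

    geom = dict(spacing=_FIG1_SPACING, origin=(0.0, 0.0, 0.0))
    return PhantomBundle(
        dose=ImageGrid(dose, **geom),
        q_activity=ImageGrid(q_act, **geom),
        v_activity=ImageGrid(v_act, **geom),
        lung=BinaryMask(lung, **geom),
    )


def _verify_figure1(bundle: PhantomBundle, alloc: dict) -> None:
    """Brute-force recount of all allocation proportions (build-time check)."""
    dose = bundle.dose.values.reshape(-1)
    lung = bundle.lung.values.reshape(-1)
    q = bundle.q_activity.values.reshape(-1)
    v = bundle.v_activity.values.reshape(-1)
    thr = 0.30 * _FIG1_ACT_IN
    n_lung = n_high = n_q = q_high = n_v = v_high = 0
    for i in range(dose.size):
        if not lung[i]:
            continue
        n_lung += 1
        hot = dose[i] >= 20.0
        n_high += hot
        if q[i] >= thr:
            n_q += 1
            q_high += hot
        if v[i] >= thr:
            n_v += 1
            v_high += hot
    got = dict(n_lung=n_lung, n_high=n_high, n_q=n_q, q_high=q_high, n_v=n_v, v_high=v_high)
    if got != alloc:
        raise AssertionError(f"figure-1 fixture inconsistent: built {got}, wanted {alloc}")


def figure1_fixture(verify: bool = True) -> dict[str, PhantomBundle]:
    """The deterministic two-case worked example (toxicity vs no toxicity)."""
    out = {}
    for name, alloc in FIGURE1_ALLOCATION.items():
        bundle = _figure1_case(alloc)
        if verify:
            _verify_figure1(bundle, alloc)
        out[name] = bundle
    return out


# --------------------------------------------------------------------------
# Cohort simulator
# --------------------------------------------------------------------------

#: Table-1-style conditional cells: covariate -> level -> (RILT, non-RILT).
TABLE1_CELLS = {
    "sex": {"male": (11, 32), "female": (4, 10)},
    "age_group": {"<70": (8, 31), ">70": (7, 11)},
    "histology": {"squamous": (11, 29), "adenocarcinoma": (4, 13)},
    "stage": {"I": (2, 4), "II": (4, 5), "III": (9, 33)},
    "location": {"central": (8, 24), "peripheral": (7, 18)},
    "copd": {"yes": (7, 13), "no": (8, 29)},
    "pft": {"worse": (5, 10), "good": (10, 32)},
    "chemo": {
        "none": (7, 24),
        "docetaxel_platinum": (2, 9),
        "pemetrexed_platinum": (2, 4),
        "gemcitabine_platinum": (4, 5),
    },
}

#: Overall (marginal) level counts implied by the conditional cells.
DEFAULT_MARGINALS = {
    cov: {lv: sum(cells) for lv, cells in levels.items()}
    for cov, levels in TABLE1_CELLS.items()
}

#: Plausible clinical ranges the latent metrics are mapped into.
METRIC_RANGES = {
    "V20": (10.0, 45.0), "Q_V20": (10.0, 45.0), "V_V20": (10.0, 45.0),
    "MLD": (8.0, 25.0), "Q_MLD": (8.0, 25.0), "V_MLD": (8.0, 25.0),
}

_METRIC_FAMILY = {
    "V20": "CT", "MLD": "CT",
    "Q_V20": "Q", "Q_MLD": "Q",
    "V_V20": "V", "V_MLD": "V",
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated cohort.

    ``rho`` is the latent Gaussian (Pearson) correlation between a metric's
    latent and the toxicity propensity; the implied metric-vs-propensity rank
    correlation is (6/pi) arcsin(rho/2). ``event_slope`` is the steepness of
    the logistic dose-response P(grade >= 2 | z); the intercept is always
    re-calibrated so the expected event count equals ``n_events``.
    """

    n_patients: int = 57
    n_events: int = 15
    marginals: dict | None = None
    rho: dict = field(default_factory=lambda: {"CT": 0.3, "Q": 0.7, "V": 0.7})
    event_slope: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 3:
            raise ValueError("need at least 3 patients")
        if not 0 < self.n_events < self.n_patients:
            raise ValueError("n_events must be strictly between 0 and n_patients")
        for fam, r in self.rho.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"rho[{fam}] must be in (-1, 1), got {r}")
        if self.marginals is not None:
            for cov, levels in self.marginals.items():
                if cov not in COVARIATE_LEVELS:
                    raise ValueError(f"unknown covariate {cov!r}")
                bad = set(levels) - set(COVARIATE_LEVELS[cov])
                if bad:
                    raise ValueError(f"unknown level(s) {bad} for covariate {cov!r}")
                total = sum(levels.values())
                if total != self.n_patients:
                    raise ValueError(
                        f"infeasible marginals for {cov!r}: counts sum to {total}, "
                        f"need {self.n_patients}"
                    )

    def effective_marginals(self) -> dict:
        """Explicit marginals, or the defaults rescaled to ``n_patients``.

        Rescaling uses largest-remainder rounding so level counts stay exact
        integers summing to the cohort size. Explicit entries override the
        rescaled defaults covariate by covariate.
        """
        out = {}
        for cov, levels in DEFAULT_MARGINALS.items():
            total = sum(levels.values())
            quotas = {lv: self.n_patients * c / total for lv, c in levels.items()}
            counts = {lv: int(np.floor(q)) for lv, q in quotas.items()}
            short = self.n_patients - sum(counts.values())
            by_remainder = sorted(
                levels, key=lambda lv: quotas[lv] - counts[lv], reverse=True
            )
            for lv in by_remainder[:short]:
                counts[lv] += 1
            out[cov] = counts
        if self.marginals is not None:
            out.update(self.marginals)
        return out

    def target_rank_correlation(self, family: str) -> float:
        """Rank correlation implied by the Gaussian copula for one family."""
        return float(6.0 / np.pi * np.arcsin(self.rho[family] / 2.0))


def _metrics_from_latent(rng: np.random.Generator, z: np.ndarray, rho: dict) -> dict:
    """Latent-copula metrics: monotone maps of rho*z + sqrt(1-rho^2)*noise."""
    out = {}
    for metric, (lo, hi) in METRIC_RANGES.items():
        r = rho[_METRIC_FAMILY[metric]]
        latent = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(z.size)
        out[metric] = lo + (hi - lo) * ndtr(latent)
    return out


def _event_probabilities(z: np.ndarray, slope: float, rate: float) -> np.ndarray:
    """Logistic event model with the intercept calibrated to the target rate."""
    a = brentq(lambda a0: expit(a0 + slope * z).mean() - rate, -60.0, 60.0)
    return expit(a + slope * z)


def _assign_grades(rng, events: np.ndarray) -> np.ndarray:
    """Grades consistent with event status: 2/3 for events, 0/1 otherwise."""
    grades = np.where(rng.random(events.size) < 0.5, 1, 0)
    severe = rng.random(events.size) < 0.2
    grades[events == 1] = np.where(severe[events == 1], 3, 2)
    return grades


def _age_for_group(rng, group: str) -> int:
    return int(rng.integers(52, 70)) if group == "<70" else int(rng.integers(71, 86))


def _records_from_parts(ids, metrics, covs, ages, grades) -> list[PatientRecord]:
    out = []
    for i, pid in enumerate(ids):
        rec_metrics = MetricRecord(**{m: float(metrics[m][i]) for m in METRIC_RANGES})
        out.append(
            PatientRecord(
                patient_id=pid, metrics=rec_metrics,
                sex=covs["sex"][i], age_years=int(ages[i]),
                histology=covs["histology"][i], stage=covs["stage"][i],
                location=covs["location"][i], copd=covs["copd"][i],
                pft=covs["pft"][i], chemo=covs["chemo"][i],
                rilt_grade=int(grades[i]),
            )
        )
    return out


def simulate_cohort_latent(spec: CohortSpec) -> tuple[list[PatientRecord], np.ndarray]:
    """Simulate a cohort and also return the latent toxicity propensity z."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    z = rng.standard_normal(n)
    metrics = _metrics_from_latent(rng, z, spec.rho)
    probs = _event_probabilities(z, spec.event_slope, spec.n_events / n)
    events = (rng.random(n) < probs).astype(int)
    grades = _assign_grades(rng, events)

    covs = {}
    for cov, counts in spec.effective_marginals().items():
        pool = [lv for lv in COVARIATE_LEVELS[cov] for _ in range(counts.get(lv, 0))]
        covs[cov] = list(np.array(pool, dtype=object)[rng.permutation(n)])
    ages = [_age_for_group(rng, covs["age_group"][i]) for i in range(n)]
    del covs["age_group"]  # derived from age_years on the record

    width = max(3, len(str(n)))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    return _records_from_parts(ids, metrics, covs, ages, grades), z


def simulate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Simulate a cohort of patient records (see :class:`CohortSpec`)."""
    return simulate_cohort_latent(spec)[0]


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    """Build a PhantomSpec from a plain (JSON-friendly) dictionary."""
    d = dict(d)
    if "lungs" in d:
        d["lungs"] = tuple(Ellipsoid(tuple(e["center_mm"]), tuple(e["radii_mm"]))
                           for e in d["lungs"])
    if "dose_fields" in d:
        d["dose_fields"] = tuple(
            BeamField(
                kind=f.get("kind", "gaussian"),
                center_mm=tuple(f["center_mm"]),
                size_mm=tuple(f["size_mm"]),
                peak_gy=float(f.get("peak_gy", 63.0)),
            )
            for f in d["dose_fields"]
        )
    if "defects" in d:
        d["defects"] = tuple(
            DefectSpec(
                modality=x["modality"],
                region=Ellipsoid(tuple(x["center_mm"]), tuple(x["radii_mm"])),
                residual=float(x.get("residual", 0.05)),
            )
            for x in d["defects"]
        )
    for key in ("shape", "spacing_mm", "origin_mm"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a plain (JSON-friendly) dictionary."""
    return CohortSpec(**d)


#: Documented default seed of the Table-1 fixture's metric columns.
TABLE1_FIXTURE_SEED = 1105


def table1_fixture(seed: int = TABLE1_FIXTURE_SEED) -> list[PatientRecord]:
    """Deterministic 57-patient cohort reproducing every Table-1-style cell.

    Event status is assigned to the 15 highest latent propensities so the
    event count is exact; each covariate is then distributed within the
    event / non-event groups to match the tabulated conditional counts.
    Metric columns come from the latent copula at the documented seed.
    """
    spec = CohortSpec(seed=seed)
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    z = rng.standard_normal(n)
    metrics = _metrics_from_latent(rng, z, spec.rho)
    order = np.argsort(-z)
    events = np.zeros(n, dtype=int)
    events[order[: spec.n_events]] = 1

    # deterministic grades: top third of events by z get grade 3, others 2;
    # upper half of non-events get grade 1, the rest 0.
    grades = np.zeros(n, dtype=int)
    ev_idx = [i for i in order if events[i]]
    for j, i in enumerate(ev_idx):
        grades[i] = 3 if j < len(ev_idx) // 3 else 2
    nev_idx = [i for i in order if not events[i]]
    for j, i in enumerate(nev_idx):
        grades[i] = 1 if j < len(nev_idx) // 2 else 0

    covs = {cov: [None] * n for cov in TABLE1_CELLS}
    for cov, level_cells in TABLE1_CELLS.items():
        for grp, idx in ((1, ev_idx), (0, nev_idx)):
            pos = 0
            for lv in COVARIATE_LEVELS[cov]:
                count = level_cells[lv][0] if grp == 1 else level_cells[lv][1]
                for _ in range(count):
                    covs[cov][idx[pos]] = lv
                    pos += 1
            assert pos == len(idx)

    ages = [
        (55 + i % 14) if covs["age_group"][i] == "<70" else (71 + i % 15)
        for i in range(n)
    ]
    del covs["age_group"]
    ids = [f"P{i + 1:03d}" for i in range(n)]
    return _records_from_parts(ids, metrics, covs, ages, grades)
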