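"""Synthetic cohort generator.

The generative model is an additive line/sex/diet/line-x-diet model per
trait family:

* body weight (grams, raw scale): intercept + sex effect + line effect
  + HFD effect (+ line-x-diet effect) + linear growth per week
  (+ extra growth on HFD) + per-animal residual.  Non-positive draws are
  rejected and redrawn.
* organ weights (liver/spleen/heart): same additive model on the log
  scale, which guarantees positivity; ``mu`` is the median weight in
  grams and the sex/diet effects are log-scale shifts.
* fasting glucose (mg/dL, raw scale): additive model; the IPGTT curve on
  top of it is a gamma pulse ``fasting + A * (t/tau) * exp(1 - t/tau)``
  plus i.i.d. measurement noise, with ``A`` and ``tau`` inflated by a
  clearance-slowing multiplier for HFD animals.  The pulse peaks at
  exactly ``fasting + A`` at ``t = tau`` and returns monotonically
  towards fasting afterwards.

Line effects are drawn once per line per trait family and shared by all
of that line's animals, so between-line variance is genuinely genetic in
the simulated sense.  Everything is driven by one integer seed through a
``numpy.random.SeedSequence`` fan-out, so a fixed seed gives a
bit-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from cc_organotrait.design import DesignError, StudyDesign, default_design

__all__ = [
    "TraitFamilyParams",
    "IpgttShape",
    "SimulationParams",
    "GlucoseCurve",
    "MouseRecord",
    "default_params",
    "generate_cohort",
    "simulate_ipgtt",
    "ipgtt_curve",
    "simulate_trait_by_line",
]

ORGANS = ("liver", "spleen", "heart")

_MAX_REJECTION_DRAWS = 1000


@dataclass(frozen=True)
class TraitFamilyParams:
    """Additive-model parameters for one trait family.

    ``diet_effect`` applies to HFD animals only; ``sigma_line`` and
    ``sigma_int`` are the s.d. of the per-line main and line-x-diet
    interaction effects; ``sigma_e`` is the per-animal residual s.d.
    """

    mu: float
    sex_effect: float = 0.0
    diet_effect: float = 0.0
    sigma_line: float = 0.0
    sigma_int: float = 0.0
    sigma_e: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_line", "sigma_int", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def implied_h2(self) -> float:
        """Target broad-sense heritability sigma_line^2/(sigma_line^2+sigma_e^2)."""
        denom = self.sigma_line**2 + self.sigma_e**2
        return float("nan") if denom == 0 else self.sigma_line**2 / denom


@dataclass(frozen=True)
class IpgttShape:
    """Gamma-pulse parameters of the glucose excursion."""

    amplitude: float = 180.0  # peak rise above fasting, mg/dL
    tau_min: float = 30.0  # time to peak, minutes
    hfd_multiplier: float = 1.35  # inflates amplitude and tau on HFD
    measurement_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValueError("tau_min must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.measurement_sd < 0:
            raise ValueError("measurement_sd must be >= 0")


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the synthetic cohort, one sub-block per trait family."""

    body_weight: TraitFamilyParams
    glucose: TraitFamilyParams
    liver: TraitFamilyParams
    spleen: TraitFamilyParams
    heart: TraitFamilyParams
    growth_per_week: float = 0.8  # grams/week, both diets
    hfd_growth_per_week: float = 0.5  # extra grams/week on HFD
    # growth-rate variability: line effect, line-x-diet effect and per-animal
    # residual on the weekly slope; this is what gives dBW its between- and
    # within-line variance (a constant intercept residual cancels in dBW)
    growth_sigma_line: float = 0.25
    growth_sigma_int: float = 0.10
    growth_sigma_e: float = 0.30
    ipgtt: IpgttShape = field(default_factory=IpgttShape)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("growth_sigma_line", "growth_sigma_int", "growth_sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def organ(self, name: str) -> TraitFamilyParams:
        if name not in ORGANS:
            raise KeyError(f"unknown organ {name!r}")
        return getattr(self, name)

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


def default_params(seed: int = 0) -> SimulationParams:
    """Defaults tuned so trait strata span implied heritabilities ~0.1-0.8."""
    return SimulationParams(
        body_weight=TraitFamilyParams(
            mu=20.0, sex_effect=4.0, diet_effect=2.0,
            sigma_line=2.0, sigma_int=0.6, sigma_e=1.5,
        ),
        glucose=TraitFamilyParams(
            mu=110.0, sex_effect=5.0, diet_effect=15.0,
            sigma_line=10.0, sigma_int=4.0, sigma_e=8.0,
        ),
        # log-scale: mu is the median organ weight in grams
        liver=TraitFamilyParams(
            mu=1.4, sex_effect=0.10, diet_effect=0.15,
            sigma_line=0.12, sigma_int=0.05, sigma_e=0.09,
        ),
        spleen=TraitFamilyParams(
            mu=0.09, sex_effect=0.05, diet_effect=0.10,
            sigma_line=0.06, sigma_int=0.04, sigma_e=0.14,
        ),
        heart=TraitFamilyParams(
            mu=0.15, sex_effect=0.06, diet_effect=-0.04,
            sigma_line=0.08, sigma_int=0.03, sigma_e=0.10,
        ),
        seed=seed,
    )


@dataclass(frozen=True)
class GlucoseCurve:
    """One IPGTT: readings (mg/dL) at the design timepoints (minutes)."""

    t_min: tuple[float, ...]
    glucose_mg_dl: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.t_min) != len(self.glucose_mg_dl):
            raise ValueError("t_min and glucose_mg_dl must have equal length")
        if any(g <= 0 for g in self.glucose_mg_dl):
            raise ValueError("glucose readings must be positive")
        if list(self.t_min) != sorted(set(self.t_min)):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class MouseRecord:
    """One animal: identity, body-weight series, IPGTT curves, terminal organs."""

    id: str
    line: str
    sex: str  # "F" or "M"
    diet: str  # "CHD" or "HFD"
    bw_g: dict[int, float]
    ipgtt: dict[int, GlucoseCurve] = field(default_factory=dict)
    organ_wt_g: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.bw_g.values()):
            raise ValueError(f"{self.id}: body weights must be positive")
        if any(w <= 0 for w in self.organ_wt_g.values()):
            raise ValueError(f"{self.id}: organ weights must be positive")


# ---------------------------------------------------------------------------
# effect machinery

_FAMILIES = ("body_weight", "glucose", "liver", "spleen", "heart")


def _draw_line_effects(
    design: StudyDesign, params: SimulationParams, rng: np.random.Generator
) -> dict[tuple[str, str], tuple[float, float]]:
    """One (main, interaction) effect pair per (line, family), in a fixed
    order so the stream is stable under seed."""
    effects: dict[tuple[str, str], tuple[float, float]] = {}
    for line in design.lines:
        for fam_name in _FAMILIES:
            fam: TraitFamilyParams = getattr(params, fam_name)
            u = rng.normal(0.0, fam.sigma_line) if fam.sigma_line > 0 else 0.0
            v = rng.normal(0.0, fam.sigma_int) if fam.sigma_int > 0 else 0.0
            effects[(line, fam_name)] = (u, v)
        gu = (
            rng.normal(0.0, params.growth_sigma_line)
            if params.growth_sigma_line > 0 else 0.0
        )
        gv = (
            rng.normal(0.0, params.growth_sigma_int)
            if params.growth_sigma_int > 0 else 0.0
        )
        effects[(line, "growth")] = (gu, gv)
    return effects


def _animal_level(
    fam: TraitFamilyParams,
    line_fx: tuple[float, float],
    sex: str,
    diet: str,
    eps: float,
) -> float:
    u, v = line_fx
    value = fam.mu + u + eps
    if sex == "M":
        value += fam.sex_effect
    if diet == "HFD":
        value += fam.diet_effect + v
    return value


def ipgtt_curve(
    fasting: float,
    diet: str,
    timepoints_min,
    shape: IpgttShape,
    rng: np.random.Generator | None = None,
) -> GlucoseCurve:
    """Gamma-pulse IPGTT curve over *timepoints_min* on top of *fasting*.

    HFD inflates both the amplitude and the time-to-peak by
    ``shape.hfd_multiplier`` (slower clearance, higher excursion).  With
    ``measurement_sd == 0`` the curve equals ``fasting`` at t=0 and peaks at
    exactly ``fasting + A_eff`` at ``t = tau_eff``.
    """
    mult = shape.hfd_multiplier if diet == "HFD" else 1.0
    amp = shape.amplitude * mult
    tau = shape.tau_min * mult
    t = np.asarray(timepoints_min, dtype=float)
    pulse = amp * (t / tau) * np.exp(1.0 - t / tau)
    values = fasting + pulse
    if shape.measurement_sd > 0:
        if rng is None:
            raise ValueError("rng required when measurement_sd > 0")
        values = values + rng.normal(0.0, shape.measurement_sd, size=t.shape)
    values = np.maximum(values, 1.0)  # glucose readings must stay positive
    return GlucoseCurve(tuple(float(x) for x in t), tuple(float(v) for v in values))


def simulate_ipgtt(
    record: MouseRecord,
    week: int,
    params: SimulationParams,
    *,
    design: StudyDesign | None = None,
    rng: np.random.Generator | None = None,
) -> GlucoseCurve:
    """Simulate one IPGTT for *record* at *week*.

    Fasting glucose is the deterministic expected level for the animal's
    sex and diet (population-level; line and animal deviations enter only
    through :func:`generate_cohort`, which uses the same curve machinery
    with per-animal fasting values).

    Raises ``KeyError`` if *week* is not an IPGTT week of the design.
    """
    if design is None:
        design = default_design()
    if week not in design.ipgtt_weeks:
        raise KeyError(f"week {week} is not an IPGTT week {design.ipgtt_weeks}")
    fam = params.glucose
    fasting = fam.mu
    if record.sex == "M":
        fasting += fam.sex_effect
    if record.diet == "HFD":
        fasting += fam.diet_effect
    return ipgtt_curve(fasting, record.diet, design.ipgtt_timepoints_min, params.ipgtt, rng)


def generate_cohort(
    design: StudyDesign, params: SimulationParams
) -> list[MouseRecord]:
    """Generate one MouseRecord per designed slot.

    Deterministic for a fixed ``params.seed``; line effects are drawn once
    per line and shared by that line's animals; HFD effects act from
    challenge week 0 onward (all recorded weeks).
    """
    ss = np.random.SeedSequence(params.seed)
    line_ss, animal_ss = ss.spawn(2)
    line_rng = np.random.default_rng(line_ss)
    rng = np.random.default_rng(animal_ss)

    effects = _draw_line_effects(design, params, line_rng)
    weeks = np.asarray(design.weeks, dtype=float)

    records: list[MouseRecord] = []
    counter = 0
    for line, sex, diet, n in design.cells():
        for k in range(n):
            counter += 1
            mouse_id = f"{line}_{sex}_{diet}_{k + 1:02d}"

            # body weight: reject series that dip non-positive
            bw_fam = params.body_weight
            gu, gv = effects[(line, "growth")]
            g_eps = (
                rng.normal(0.0, params.growth_sigma_e)
                if params.growth_sigma_e > 0 else 0.0
            )
            growth = params.growth_per_week + gu + g_eps
            if diet == "HFD":
                growth += params.hfd_growth_per_week + gv
            for _ in range(_MAX_REJECTION_DRAWS):
                eps = rng.normal(0.0, bw_fam.sigma_e) if bw_fam.sigma_e > 0 else 0.0
                base = _animal_level(bw_fam, effects[(line, "body_weight")], sex, diet, eps)
                series = base + growth * weeks
                if np.all(series > 0):
                    break
            else:  # pragma: no cover - pathological parameters
                raise RuntimeError(
                    f"could not draw a positive body-weight series for {mouse_id}"
                )
            bw = {int(w): float(v) for w, v in zip(design.weeks, series)}

            # fasting glucose + IPGTT curves
            glu_fam = params.glucose
            g_eps = rng.normal(0.0, glu_fam.sigma_e) if glu_fam.sigma_e > 0 else 0.0
            fasting = _animal_level(glu_fam, effects[(line, "glucose")], sex, diet, g_eps)
            fasting = max(fasting, 40.0)  # physiological floor
            curves = {
                int(week): ipgtt_curve(
                    fasting, diet, design.ipgtt_timepoints_min, params.ipgtt, rng
                )
                for week in design.ipgtt_weeks
            }

            # terminal organ weights, log-scale additive model
            organs: dict[str, float] = {}
            for organ in ORGANS:
                fam = params.organ(organ)
                o_eps = rng.normal(0.0, fam.sigma_e) if fam.sigma_e > 0 else 0.0
                log_w = _animal_level(
                    replace(fam, mu=math.log(fam.mu)),
                    effects[(line, organ)],
                    sex,
                    diet,
                    o_eps,
                )
                organs[organ] = float(math.exp(log_w))

            records.append(
                MouseRecord(
                    id=mouse_id, line=line, sex=sex, diet=diet,
                    bw_g=bw, ipgtt=curves, organ_wt_g=organs,
                )
            )
    return records


def simulate_trait_by_line(
    n_lines: int,
    n_per_line: int,
    *,
    mu: float = 0.0,
    sigma_line: float,
    sigma_e: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Fast path for estimator-calibration studies: draw one trait under the
    one-way random-effects model (line effects N(0, sigma_line^2), residuals
    N(0, sigma_e^2)) without building full MouseRecords.
    """
    out: dict[str, np.ndarray] = {}
    line_fx = rng.normal(0.0, sigma_line, size=n_lines)
    for i in range(n_lines):
        out[f"L{i:03d}"] = mu + line_fx[i] + rng.normal(0.0, sigma_e, size=n_per_line)
    return out
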