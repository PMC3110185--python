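"""Synthetic plate-format screen generator.

Emulates a 96-well adherent ES-cell differentiation/cytotoxicity screen read
out by a two-channel In-Cell Western: channel 700 carries the cell-number
stain, channel 800 the cardiomyocyte (myosin heavy chain) stain. Chemicals
act through Hill-shaped concentration responses on two independent axes —
relative cell number and cytotoxicity-corrected differentiation — and every
generated screen ships with a ground-truth table so downstream parameter
recovery can be scored.

The generator's defaults mirror the screening regime the analysis assumes:
eight chemicals per plate, one per row, in duplicate wells at four
concentrations spanning 0.0125–12.5 µM, vehicle and no-stain control wells
on every plate, multiplicative log-normal intensity noise at the 5% level,
and an additive background near 5% of the vehicle signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

VEHICLE = "VEHICLE"
NOSTAIN = "NOSTAIN"

CELL_AXIS = "cell_number"
DIFF_AXIS = "differentiation"

#: endpoint label -> (axis, direction)
ENDPOINT_AXES = {
    "cell_loss": (CELL_AXIS, "down"),
    "cell_gain": (CELL_AXIS, "up"),
    "diff_decrease": (DIFF_AXIS, "down"),
    "diff_increase": (DIFF_AXIS, "up"),
}

DEFAULT_CONCENTRATIONS = (0.0125, 0.125, 1.25, 12.5)


class LayoutError(ValueError):
    """Chemicals do not fit the plate layout."""


class ValidationError(ValueError):
    """Invalid simulation parameters."""


def hill(c, ac50, slope):
    """Fractional Hill occupancy c^h / (c^h + ac50^h), 0 at c=0, ->1 as c->inf."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        x = (c / ac50) ** slope
    return x / (1.0 + x)


@dataclass(frozen=True)
class Effect:
    """One chemical effect on one endpoint axis.

    ``endpoint`` is one of cell_loss / cell_gain / diff_decrease /
    diff_increase / ushape / none.  For ``ushape`` the axis must be named
    explicitly; the response is a gain term at low concentration plus a
    dominating loss term at high concentration, which produces excursions on
    both sides of the control band and no 50%-change concentration.
    """

    endpoint: str
    true_ac50: float = 1.0  # µM, Hill midpoint parameter
    hill_slope: float = 1.0
    max_effect: float = 1.0  # fraction lost (losses) or fractional gain (gains)
    axis: str | None = None  # required for ushape

    def __post_init__(self):
        known = set(ENDPOINT_AXES) | {"ushape", "none"}
        if self.endpoint not in known:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.endpoint != "none":
            if not self.true_ac50 > 0:
                raise ValidationError("true_ac50 must be > 0")
            if not self.hill_slope > 0:
                raise ValidationError("hill_slope must be > 0")
            if self.max_effect < 0:
                raise ValidationError("max_effect must be >= 0")
            if self.endpoint in ("cell_loss", "diff_decrease") and self.max_effect > 1:
                raise ValidationError("loss max_effect must lie in [0, 1]")
        if self.endpoint == "ushape" and self.axis not in (CELL_AXIS, DIFF_AXIS):
            raise ValidationError("ushape effects must name an axis")

    @property
    def effect_axis(self) -> str | None:
        if self.endpoint == "none":
            return None
        if self.endpoint == "ushape":
            return self.axis
        return ENDPOINT_AXES[self.endpoint][0]

    def response(self, conc):
        """Vehicle-relative response of this effect's axis at concentration(s)."""
        conc = np.asarray(conc, dtype=float)
        if self.endpoint == "none":
            return np.ones_like(conc)
        if self.endpoint == "ushape":
            # gain below the midpoint, dominating loss above it
            up = self.max_effect * hill(conc, self.true_ac50 / 5.0, self.hill_slope)
            down = (self.max_effect + 0.8) * hill(conc, self.true_ac50 * 5.0, self.hill_slope)
            return 1.0 + up - down
        frac = self.max_effect * hill(conc, self.true_ac50, self.hill_slope)
        _, direction = ENDPOINT_AXES[self.endpoint]
        return 1.0 - frac if direction == "down" else 1.0 + frac

    def ac50_change(self) -> float | None:
        """True 50%-change concentration (µM), or None if never attained.

        The analysis defines AC50 as the concentration producing a 50%
        change from control, which coincides with the Hill midpoint only at
        full efficacy; for max_effect m > 0.5 it is
        ac50 * (0.5 / (m - 0.5))**(1/h).
        """
        if self.endpoint in ("none", "ushape"):
            return None
        m = self.max_effect
        if m <= 0.5:
            return None
        return self.true_ac50 * (0.5 / (m - 0.5)) ** (1.0 / self.hill_slope)


@dataclass(frozen=True)
class TruthChemical:
    """Simulator ground truth for one chemical: at most one effect per axis."""

    name: str
    effects: tuple[Effect, ...] = ()

    def __post_init__(self):
        axes = [e.effect_axis for e in self.effects if e.effect_axis is not None]
        if len(axes) != len(set(axes)):
            raise ValidationError(f"{self.name}: more than one effect on an axis")

    def axis_response(self, axis: str, conc):
        for e in self.effects:
            if e.effect_axis == axis:
                return e.response(conc)
        return np.ones_like(np.asarray(conc, dtype=float))


@dataclass(frozen=True)
class PlateLayoutSpec:
    """96-well layout: one chemical per row, duplicate wells as column pairs.

    Columns ``0..2*len(concentrations)-1`` hold treated wells (two adjacent
    columns per concentration), ``vehicle_cols`` hold 0-concentration DMSO
    controls and ``nostain_cols`` hold stain/antibody-free background wells.
    """

    n_rows: int = 8
    n_cols: int = 12
    chemicals_per_plate: int = 8
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    vehicle_cols: tuple[int, ...] = (8, 9)
    nostain_cols: tuple[int, ...] = (10, 11)
    n_duplicates: int = 2

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(conc <= 0):
            raise ValidationError("concentrations must be positive")
        if np.any(np.diff(conc) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        if len(self.vehicle_cols) == 0:
            raise ValidationError("vehicle_cols must be nonempty")
        if self.chemicals_per_plate > self.n_rows:
            raise LayoutError("chemicals_per_plate exceeds available rows")
        n_treat = self.n_duplicates * len(self.concentrations)
        treated = set(range(n_treat))
        if treated & set(self.nostain_cols) or set(self.vehicle_cols) & set(self.nostain_cols):
            raise ValidationError("no-stain wells overlap treated/vehicle wells")
        if n_treat + len(self.vehicle_cols) + len(self.nostain_cols) > self.n_cols:
            raise LayoutError("layout does not fit the plate width")

    @property
    def treated_cols(self) -> tuple[int, ...]:
        return tuple(range(self.n_duplicates * len(self.concentrations)))

    def conc_of_col(self, col: int) -> float:
        return self.concentrations[col // self.n_duplicates]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal channel noise plus additive Gaussian background.

    cv_intensity is the coefficient of variation of the per-channel
    multiplicative noise (mean-one log-normal); background_mean/background_sd
    parameterize the additive background intensity shared by every well.
    """

    cv_intensity: float = 0.05
    background_mean: float = 500.0  # 5% of the default vehicle intensity
    background_sd: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.cv_intensity < 0:
            raise ValidationError("cv_intensity must be >= 0")
        if self.background_sd < 0:
            raise ValidationError("background_sd must be >= 0")

    def multiplicative(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.cv_intensity == 0:
            return np.ones(size)
        sigma = math.sqrt(math.log1p(self.cv_intensity**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    def background(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.background_mean == 0 and self.background_sd == 0:
            return np.zeros(size)
        return np.clip(rng.normal(self.background_mean, self.background_sd, size=size), 0.0, None)


ZERO_NOISE = NoiseModel(cv_intensity=0.0, background_mean=0.0, background_sd=0.0)

WELL_COLUMNS = [
    "plate_id", "row", "col", "chemical", "conc_uM",
    "channel700", "channel800", "is_vehicle", "is_nostain",
]


def generate_plate(
    spec: PlateLayoutSpec,
    chems: list[TruthChemical],
    noise: NoiseModel,
    plate_id: str = "P1",
    vehicle_intensity: float = 10_000.0,
    baseline_ratio: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one plate of two-channel well intensities.

    Expected (noise-free) signals: a treated well's channel 700 is the
    vehicle intensity times the chemical's cell-number response; channel 800
    is channel 700 times the differentiation response times the baseline
    800/700 ratio. No-stain wells carry background only.
    """
    if len(chems) > spec.chemicals_per_plate:
        raise LayoutError(
            f"{len(chems)} chemicals exceed {spec.chemicals_per_plate} per plate"
        )
    names = [c.name for c in chems]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate chemical names on one plate")
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    rows = []
    for r in range(spec.n_rows):
        chem = chems[r] if r < len(chems) else None
        for col in range(spec.n_cols):
            if col in spec.nostain_cols:
                rows.append((plate_id, r, col, NOSTAIN, 0.0, 0.0, 0.0, False, True))
            elif col in spec.vehicle_cols:
                s700 = vehicle_intensity
                rows.append((plate_id, r, col, VEHICLE, 0.0, s700,
                             s700 * baseline_ratio, True, False))
            elif chem is not None and col in spec.treated_cols:
                conc = spec.conc_of_col(col)
                cell = float(chem.axis_response(CELL_AXIS, conc))
                diff = float(chem.axis_response(DIFF_AXIS, conc))
                s700 = vehicle_intensity * cell
                s800 = s700 * diff * baseline_ratio
                rows.append((plate_id, r, col, chem.name, conc, s700, s800, False, False))
    wells = pd.DataFrame(rows, columns=WELL_COLUMNS)

    n = len(wells)
    signal = wells[["channel700", "channel800"]].to_numpy()
    noisy = signal * noise.multiplicative(rng, (n, 2)) + noise.background(rng, (n, 2))
    wells[["channel700", "channel800"]] = noisy
    return wells


@dataclass(frozen=True)
class TruthSampler:
    """Parameter ranges for drawing ground-truth chemicals.

    Half the library is inactive by default; active chemicals draw their
    Hill midpoint log-uniformly over the central tested range (0.05–5 µM so
    four-point curves are identifiable), slopes in [0.8, 2], and efficacies
    in [0.7, 1] so the true curve attains a 50% change. Endpoint-direction
    weights follow the screen's observed preponderance of decreased cell
    number and decreased differentiation; a small U-shape fraction mirrors
    the rarity of nonmonotone responses.
    """

    p_inactive: float = 0.5
    ac50_range: tuple[float, float] = (0.05, 5.0)
    slope_range: tuple[float, float] = (0.8, 2.0)
    max_effect_range: tuple[float, float] = (0.7, 1.0)
    cell_weights: tuple[float, float, float] = (0.43, 0.45, 0.12)  # none/loss/gain
    diff_weights: tuple[float, float, float] = (0.56, 0.38, 0.06)  # none/decrease/increase
    p_ushape: float = 0.02

    def __post_init__(self):
        for lo, hi in (self.ac50_range, self.slope_range, self.max_effect_range):
            if not (0 < lo <= hi):
                raise ValidationError("empty or non-positive parameter range")

    def _draw_effect(self, rng, endpoint, axis=None) -> Effect:
        lo, hi = self.ac50_range
        ac50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        slope = float(rng.uniform(*self.slope_range))
        me = float(rng.uniform(*self.max_effect_range))
        return Effect(endpoint, ac50, slope, me, axis=axis)

    def sample(self, rng: np.random.Generator, name: str) -> TruthChemical:
        if rng.uniform() < self.p_inactive:
            return TruthChemical(name, ())
        if rng.uniform() < self.p_ushape:
            axis = CELL_AXIS if rng.uniform() < 0.5 else DIFF_AXIS
            return TruthChemical(name, (self._draw_effect(rng, "ushape", axis=axis),))
        while True:
            cell = rng.choice(3, p=self.cell_weights)
            diff = rng.choice(3, p=self.diff_weights)
            if cell or diff:
                break
        effects = []
        if cell:
            effects.append(self._draw_effect(rng, "cell_loss" if cell == 1 else "cell_gain"))
        if diff:
            effects.append(self._draw_effect(rng, "diff_decrease" if diff == 1 else "diff_increase"))
        return TruthChemical(name, tuple(effects))


def truth_table(chems: list[TruthChemical]) -> pd.DataFrame:
    """Long-format ground truth, one row per chemical effect.

    ``ac50_change_uM`` is the true 50%-change concentration (NaN when the
    effect never attains a 50% change, e.g. U-shapes).
    """
    rows = []
    for chem in chems:
        if not chem.effects or all(e.endpoint == "none" for e in chem.effects):
            rows.append((chem.name, "none", np.nan, np.nan, np.nan, np.nan))
            continue
        for e in chem.effects:
            if e.endpoint == "none":
                continue
            change = e.ac50_change()
            rows.append((
                chem.name,
                e.endpoint if e.endpoint != "ushape" else f"ushape_{e.axis}",
                e.true_ac50, e.hill_slope, e.max_effect,
                np.nan if change is None else change,
            ))
    return pd.DataFrame(
        rows,
        columns=["chemical", "endpoint", "true_ac50_uM", "hill_slope", "max_effect",
                 "ac50_change_uM"],
    )


def generate_screen(
    n_chemicals: int,
    truth_sampler: TruthSampler | None = None,
    spec: PlateLayoutSpec | None = None,
    noise: NoiseModel | None = None,
    n_triplicates: int = 0,
    **plate_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a multi-plate screen plus its ground-truth table.

    Returns ``(wells, truth)``. The first ``n_triplicates`` chemicals are
    plated three times (plating replicates for CV checks); plates are filled
    eight row-slots at a time, so the screen spans
    ceil((n_chemicals + 2*n_triplicates) / chemicals_per_plate) plates.
    """
    if n_chemicals < 1:
        raise ValidationError("n_chemicals must be >= 1")
    truth_sampler = truth_sampler or TruthSampler()
    spec = spec or PlateLayoutSpec()
    noise = noise or NoiseModel()
    if n_triplicates > n_chemicals:
        raise ValidationError("n_triplicates exceeds n_chemicals")

    rng = np.random.default_rng(noise.seed)
    chems = [truth_sampler.sample(rng, f"CHEM{i + 1:03d}") for i in range(n_chemicals)]

    slots: list[TruthChemical] = list(chems)
    for chem in chems[:n_triplicates]:
        slots.extend([chem, chem])

    per = spec.chemicals_per_plate
    plates = []
    for p in range(math.ceil(len(slots) / per)):
        batch = slots[p * per:(p + 1) * per]
        plates.append(
            _generate_plate_allow_repeats(spec, batch, noise, f"P{p + 1}", rng, **plate_kwargs)
        )
    wells = pd.concat(plates, ignore_index=True)
    return wells, truth_table(chems)


def _generate_plate_allow_repeats(spec, chems, noise, plate_id, rng, **kw):
    """generate_plate, but tolerant of the same chemical occupying two rows."""
    unique = len({c.name for c in chems}) == len(chems)
    if unique:
        return generate_plate(spec, chems, noise, plate_id, rng=rng, **kw)
    parts = []
    for i, chem in enumerate(chems):
        sub = PlateLayoutSpec(
            n_rows=1, n_cols=spec.n_cols, chemicals_per_plate=1,
            concentrations=spec.concentrations, vehicle_cols=spec.vehicle_cols,
            nostain_cols=spec.nostain_cols, n_duplicates=spec.n_duplicates,
        )
        part = generate_plate(sub, [chem], noise, plate_id, rng=rng, **kw)
        part["row"] = i
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def write_screen(wells: pd.DataFrame, truth: pd.DataFrame, wells_path, truth_path) -> None:
    wells.to_csv(wells_path, index=False)
    truth.to_csv(truth_path, index=False)


def generate_external_assays(
    truth: pd.DataFrame,
    n_assays: int = 8,
    seed: int = 0,
    p_linked: float = 0.8,
    p_background: float = 0.1,
    jitter_dex: float = 0.25,
) -> pd.DataFrame:
    """Synthetic external-assay AC50 columns correlated with screen truth.

    Emulates a broader assay suite run on the same chemical library: each
    assay is linked to one screen endpoint (round-robin over the four), and
    a chemical truly active on that endpoint is active in the assay with
    probability ``p_linked`` at an AC50 within ``jitter_dex`` decades of its
    true 50%-change concentration; unlinked chemicals show background
    activity with probability ``p_background`` at a random potency. Values
    are molar with the 1 M inactive default, indexed by chemical.
    """
    rng = np.random.default_rng(seed)
    chemicals = list(dict.fromkeys(truth["chemical"]))
    endpoints = list(ENDPOINT_AXES)
    truth_ac50 = {
        (r.chemical, r.endpoint): r.ac50_change_uM
        for r in truth.itertuples()
        if r.endpoint in ENDPOINT_AXES and np.isfinite(r.ac50_change_uM)
    }
    out = {}
    for j in range(n_assays):
        linked = endpoints[j % len(endpoints)]
        col = np.ones(len(chemicals))
        for i, chem in enumerate(chemicals):
            ac50_uM = truth_ac50.get((chem, linked))
            if ac50_uM is not None and rng.uniform() < p_linked:
                col[i] = ac50_uM * 1e-6 * 10.0 ** rng.normal(0.0, jitter_dex)
            elif rng.uniform() < p_background:
                col[i] = 10.0 ** rng.uniform(-8.0, -5.0)
        out[f"assay_{j + 1:02d}_{linked}"] = col
    return pd.DataFrame(out, index=pd.Index(chemicals, name="chemical"))
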