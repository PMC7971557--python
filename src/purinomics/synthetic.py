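"""Synthetic-data generators emulating an acute-hyperpurinergia study.

Every downstream stage of the pipeline can be exercised without animal
data: the generators produce sample x metabolite AUC tables, indirect
calorimetry traces, dose-response tables, longitudinal temperature series
and breath-canister tables with the statistical structure the analysis
assumes.

The metabolome model is lognormal: log2 AUCs are normal with a
per-metabolite control mean and SD, treated samples are shifted by
``effect_z`` control-SD units, and superclusters add a shared latent
factor on the log2 scale so coordinated change is genuine correlation,
not merely equal means.  Default study-scale dimensions are 401
metabolites in 37 pathways with n = 8 per group; physiology defaults
mirror the measured feature table (e.g. saline VO2 5302 +/- 710 ml/kg/hr
dropping 74% after ATP, temperature dose-response slopes -27.8 (F) /
-16.5 (M) degC per umol/g, and a +0.8 degC rebound over days 6-14 in
primed animals).

Each generator call consumes exactly one explicitly seeded pseudo-random
stream; there is no global random state, and equal seeds give bitwise
identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MetaboliteMatrix
from .physiology import CalorimetryTrace, TemperatureSeries


def _spread(n: int, mean: float, sd: float) -> np.ndarray:
    """Deterministic values with exactly the requested mean and sample SD."""
    if n == 1:
        return np.array([mean])
    base = np.linspace(-1.0, 1.0, n)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


# ---------------------------------------------------------------------------
# Metabolome


@dataclass
class MetabolomeSpec:
    """Recipe for a synthetic sample x metabolite AUC table.

    ``metabolites`` columns: name, pathway, effect_z (treated displacement
    in measured control-SD units, i.e. the z-score the pipeline should
    observe), log2_mean, log2_sd, supercluster (int label or -1 for none).  ``supercluster_loading`` scales the shared latent factor
    added (in units of each member's control SD) to treated samples of a
    supercluster.
    """

    n_control: int
    n_treated: int
    metabolites: pd.DataFrame
    supercluster_loading: float = 0.5
    control_label: str = "saline"
    treated_label: str = "ATP_30min"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_control < 3:
            raise ValueError(f"n_control must be >= 3, got {self.n_control}")
        if self.n_treated < 3:
            raise ValueError(f"n_treated must be >= 3, got {self.n_treated}")
        required = {"name", "pathway", "effect_z", "log2_mean", "log2_sd"}
        missing = required - set(self.metabolites.columns)
        if missing:
            raise ValueError(f"metabolites table missing columns {sorted(missing)}")
        if "supercluster" not in self.metabolites.columns:
            self.metabolites = self.metabolites.assign(supercluster=-1)
        if self.metabolites["name"].duplicated().any():
            dup = self.metabolites.loc[self.metabolites["name"].duplicated(), "name"]
            raise ValueError(f"duplicate metabolite name {dup.iloc[0]!r}")
        sd = self.metabolites["log2_sd"].to_numpy(dtype=float)
        if np.any(~(sd > 0)):
            bad = self.metabolites.loc[~(sd > 0), "name"].iloc[0]
            raise ValueError(f"log2_sd must be positive (metabolite {bad!r})")
        eff = self.metabolites["effect_z"].to_numpy(dtype=float)
        if np.any(~np.isfinite(eff)):
            bad = self.metabolites.loc[~np.isfinite(eff), "name"].iloc[0]
            raise ValueError(f"effect_z must be finite (metabolite {bad!r})")
        if (self.metabolites["pathway"].astype(str) == "").any():
            raise ValueError("every metabolite needs a non-empty pathway")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)


def simulate_metabolome(spec: MetabolomeSpec) -> MetaboliteMatrix:
    """Draw a positive, complete AUC table from a MetabolomeSpec.

    Control log2 values are N(log2_mean, log2_sd).  ``effect_z`` is the
    target displacement in *measured* control-SD units, so treated values
    are shifted by effect_z times the realized control-sample SD (not the
    population value): the control-referenced z-score computed downstream
    is then an unbiased estimate of effect_z even at n = 8, where the
    sample SD's reciprocal is noticeably biased upward (E[sigma/s] = 1.13
    at 7 df).  Supercluster members additionally share a per-sample latent
    factor scaled by loading * SD.  There are no missing values.  Equal
    seeds give identical tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    met = spec.metabolites
    p = len(met)
    mu = met["log2_mean"].to_numpy(dtype=float)
    sd = met["log2_sd"].to_numpy(dtype=float)
    eff = met["effect_z"].to_numpy(dtype=float)
    ctrl = rng.normal(mu, sd, size=(spec.n_control, p))
    s_hat = ctrl.std(axis=0, ddof=1)
    s_hat = np.where(s_hat > 0, s_hat, sd)
    trt = rng.normal(mu + eff * s_hat, sd, size=(spec.n_treated, p))
    clusters = met["supercluster"].to_numpy()
    for cid in np.unique(clusters):
        if cid < 0:
            continue
        members = clusters == cid
        latent = rng.normal(0.0, 1.0, size=spec.n_treated)
        trt[:, members] += (
            spec.supercluster_loading * np.outer(latent, s_hat[members])
        )
    log2 = np.vstack([ctrl, trt])
    samples = [f"ctrl_{i + 1:02d}" for i in range(spec.n_control)] + [
        f"trt_{i + 1:02d}" for i in range(spec.n_treated)
    ]
    auc = pd.DataFrame(np.exp2(log2), index=samples, columns=met["name"].tolist())
    groups = pd.Series(
        [spec.control_label] * spec.n_control + [spec.treated_label] * spec.n_treated,
        index=samples,
        name="group",
    )
    pathways = pd.Series(
        met["pathway"].astype(str).to_numpy(), index=met["name"].tolist(),
        name="pathway",
    )
    return MetaboliteMatrix(auc=auc, groups=groups, pathways=pathways)


def simple_metabolome_spec(
    n_metabolites: int,
    n_control: int = 8,
    n_treated: int = 8,
    effect_z: float | np.ndarray = 0.0,
    n_pathways: int = 4,
    seed: int = 0,
    **kwargs,
) -> MetabolomeSpec:
    """Small flat spec: metabolites met_000.. spread over generic pathways."""
    eff = np.broadcast_to(np.asarray(effect_z, dtype=float), (n_metabolites,))
    met = pd.DataFrame(
        {
            "name": [f"met_{i:03d}" for i in range(n_metabolites)],
            "pathway": [f"pathway_{i % n_pathways:02d}" for i in range(n_metabolites)],
            "effect_z": eff,
            "log2_mean": np.linspace(12.0, 24.0, n_metabolites),
            "log2_sd": np.linspace(0.4, 1.0, n_metabolites),
            "supercluster": -1,
        }
    )
    return MetabolomeSpec(
        n_control=n_control, n_treated=n_treated, metabolites=met, seed=seed, **kwargs
    )


def _slug(pathway: str) -> str:
    out = pathway.lower()
    for ch in "()&":
        out = out.replace(ch, "")
    return "_".join(out.split())


def study_metabolome_spec(
    n_control: int = 8,
    n_treated: int = 8,
    seed: int = 0,
    supercluster_loading: float = 0.5,
) -> MetabolomeSpec:
    """Study-scale default: 401 metabolites, 37 pathways, n = 8 + 8.

    Plants the acute 30-minute response structure: a decreased supercluster
    (cluster 0, 63 metabolites averaging z ~ -3.4, containing all 19 amino
    acids at mean -5.0 with SD 2.6), an increased supercluster (cluster 1,
    71 metabolites averaging z ~ +3.2, containing 11 microbiome metabolites
    at mean +3.5), a set of moderate responders around |z| ~ 2, and null
    metabolites for the remainder.
    """
    rows: list[dict] = []

    def add(pathway: str, count: int, effects: np.ndarray, cluster) -> None:
        clusters = cluster if hasattr(cluster, "__len__") else [cluster] * count
        for i in range(count):
            rows.append(
                {
                    "name": f"{_slug(pathway)}_{i + 1:02d}",
                    "pathway": pathway,
                    "effect_z": float(effects[i]),
                    "supercluster": int(clusters[i]),
                }
            )

    # Decreased supercluster (0): 19 amino acids at -5.0 +/- 2.6 plus 44
    # lipid-class members chosen so the 63-member mean is -3.4.
    aa_eff = _spread(19, -5.0, 2.6)
    rest_total = 63 * -3.4 - aa_eff.sum()
    down_members = [("Ceramides", 15), ("Bis(monoacylglycero)phosphates", 6),
                    ("Phosphatidylinositols", 10), ("Phosphatidylethanolamines", 8),
                    ("Acyl-carnitines", 5)]
    n_down = sum(n for _, n in down_members)
    down_eff = _spread(n_down, rest_total / n_down, 1.2)
    add("Amino acids", 19, aa_eff, 0)
    start = 0
    for pathway, count in down_members:
        add(pathway, count, down_eff[start : start + count], 0)
        start += count

    # Increased supercluster (1): 11 microbiome metabolites at +3.5 +/- 1.5
    # plus 60 members chosen so the 71-member mean is +3.2.
    micro_eff = _spread(11, 3.5, 1.5)
    up_members = [("Purines", 16), ("Vitamins & cofactors", 12), ("Eicosanoids", 11),
                  ("Glycolysis", 8), ("TCA cycle", 8),
                  ("Phospholipid head groups", 5)]
    n_up = sum(n for _, n in up_members)
    up_eff = _spread(n_up, (71 * 3.2 - micro_eff.sum()) / n_up, 1.6)
    micro_all = np.concatenate([micro_eff, _spread(2, -1.2, 0.4)])
    add("Microbiome metabolites", 13, micro_all, [1] * 11 + [-1, -1])
    start = 0
    for pathway, count in up_members:
        add(pathway, count, up_eff[start : start + count], 1)
        start += count

    # Moderate responders outside the two superclusters.
    moderate = [("One-carbon & folate", 8, -2.2), ("Bile acids", 8, -1.8),
                ("Sphingomyelins", 12, -1.5), ("Cholesterol & sterols", 9, -1.4),
                ("Pyrimidines", 8, 1.6), ("Polyamines", 7, 1.5),
                ("Urea cycle", 7, 1.6), ("Neurotransmitters", 8, 1.8),
                ("Glutathione & redox", 9, 1.7)]
    for pathway, count, mean in moderate:
        add(pathway, count, _spread(count, mean, 0.4), -1)

    # Null pathways fill out 401 metabolites / 37 pathways.
    n_so_far = len(rows)
    n_named = len({r["pathway"] for r in rows})
    n_null_pathways = 37 - n_named
    n_null = 401 - n_so_far
    sizes = np.full(n_null_pathways, n_null // n_null_pathways)
    sizes[: n_null % n_null_pathways] += 1
    for k, size in enumerate(sizes):
        add(f"Background pathway {k + 1:02d}", int(size),
            np.zeros(int(size)), -1)

    met = pd.DataFrame(rows)
    p = len(met)
    met["log2_mean"] = np.linspace(12.0, 24.0, p)
    met["log2_sd"] = np.linspace(0.35, 0.95, p)
    return MetabolomeSpec(
        n_control=n_control,
        n_treated=n_treated,
        metabolites=met,
        supercluster_loading=supercluster_loading,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Calorimetry


@dataclass
class CalorimetryGroupSpec:
    """Per-group post-injection means and between-animal SDs."""

    n: int
    vo2_mean: float
    vo2_sd: float
    vco2_mean: float
    vco2_sd: float
    activity_mean: float = 50.0
    activity_sd: float = 0.0

    def validate(self, name: str) -> None:
        if self.n < 1:
            raise ValueError(f"group {name!r}: n must be >= 1")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_mean") and v < 0:
                raise ValueError(f"group {name!r}: {f.name} must be non-negative")
            if f.name.endswith("_sd") and v < 0:
                raise ValueError(f"group {name!r}: {f.name} must be non-negative")


@dataclass
class CalorimetrySpec:
    """Recipe for interval-level calorimetry traces.

    Treated groups sit at the control (baseline) means before
    ``injection_min`` and at their own post-injection means afterwards.
    ``within_sd_frac`` scales interval-to-interval noise as a fraction of
    the local mean; between-animal scatter uses the stated group SDs.
    ``gas_correlation`` couples an animal's VO2 and VCO2 offsets (a large
    animal burns and exhales more of both); 0.7 reproduces a respiratory
    exchange ratio spread of roughly 0.08 at the stated gas-rate SDs.
    """

    groups: dict
    control_group: str = "saline"
    interval_min: float = 13.0
    duration_min: float = 180.0
    injection_min: float = 0.0
    within_sd_frac: float = 0.05
    gas_correlation: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.control_group not in self.groups:
            raise ValueError(f"control group {self.control_group!r} not in groups")
        for name, g in self.groups.items():
            g.validate(name)
        if self.interval_min <= 0 or self.duration_min <= 0:
            raise ValueError("interval and duration must be positive")
        if self.within_sd_frac < 0:
            raise ValueError("within_sd_frac must be non-negative")
        if not (-1 <= self.gas_correlation <= 1):
            raise ValueError("gas_correlation must lie in [-1, 1]")


def simulate_calorimetry(spec: CalorimetrySpec) -> list[CalorimetryTrace]:
    """One 3-hour trace of 13-minute intervals per animal.

    With all SDs and ``within_sd_frac`` zero, every interval equals the
    spec mean exactly.  Gas rates are floored at a small positive value to
    respect the positivity invariant of downstream ratios.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    starts = np.arange(0.0, spec.duration_min, spec.interval_min)
    ctrl = spec.groups[spec.control_group]
    traces = []
    for gname in sorted(spec.groups):
        g = spec.groups[gname]
        for i in range(g.n):
            z1, z2 = rng.normal(size=2)
            rho = spec.gas_correlation
            offsets = {
                "vo2": g.vo2_sd * z1,
                "vco2": g.vco2_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2),
                "activity": rng.normal(0.0, g.activity_sd) if g.activity_sd > 0 else 0.0,
            }
            rows = []
            for s in starts:
                pre = gname != spec.control_group and s < spec.injection_min
                base = ctrl if pre else g
                vals = {}
                for key, mean in (
                    ("vo2", base.vo2_mean), ("vco2", base.vco2_mean),
                    ("activity", base.activity_mean),
                ):
                    v = mean + offsets[key]
                    if spec.within_sd_frac > 0:
                        v += rng.normal(0.0, spec.within_sd_frac * max(mean, 1e-12))
                    vals[key] = v
                rows.append(
                    {
                        "start_min": s,
                        "vo2": max(vals["vo2"], 1e-3),
                        "vco2": max(vals["vco2"], 1e-3),
                        "beam_breaks": max(vals["activity"], 0.0),
                    }
                )
            traces.append(
                CalorimetryTrace(
                    animal=f"{gname}_{i + 1:02d}",
                    group=gname,
                    intervals=pd.DataFrame(rows),
                )
            )
    return traces


def study_calorimetry_spec(seed: int = 0, injection_min: float = 13.0
                           ) -> CalorimetrySpec:
    """Feature-table-scale defaults: saline VO2 5302 +/- 710 and VCO2
    4324 +/- 647 ml/kg/hr vs ATP 1382 +/- 325 and 1034 +/- 226, n = 6."""
    return CalorimetrySpec(
        groups={
            "saline": CalorimetryGroupSpec(
                n=6, vo2_mean=5302, vo2_sd=710, vco2_mean=4324, vco2_sd=647,
                activity_mean=60, activity_sd=35,
            ),
            "ATP": CalorimetryGroupSpec(
                n=6, vo2_mean=1382, vo2_sd=325, vco2_mean=1034, vco2_sd=226,
                activity_mean=2, activity_sd=1.3,
            ),
        },
        injection_min=injection_min,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Dose-response


def simulate_dose_response(
    slope_beta: float,
    intercept: float,
    doses,
    n_per_dose: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    sex: str = "female",
) -> pd.DataFrame:
    """Linear dose-response table: response = intercept + slope * dose + noise.

    ``slope_beta`` is in response units per umol/g (e.g. degC per umol/g
    ATP for 15-minute temperatures); returns columns sex, dose, response.
    """
    doses = np.asarray(list(doses), dtype=float)
    if doses.size == 0:
        raise ValueError("dose list is empty")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if n_per_dose < 2:
        raise ValueError(f"n_per_dose must be >= 2, got {n_per_dose}")
    rng = np.random.default_rng(seed)
    dose_col = np.repeat(doses, n_per_dose)
    response = intercept + slope_beta * dose_col
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=dose_col.size)
    return pd.DataFrame({"sex": sex, "dose": dose_col, "response": response})


#: Temperature dose-response slopes (degC per umol/g ATP, 15 min post-injection).
STUDY_TEMP_SLOPES = {"female": -27.8, "male": -16.5}
#: Behavioral (PBRS) dose-response slopes (PBRS units per umol/g ATP).
STUDY_PBRS_SLOPES = {"male": 37.1, "female": 27.4}
#: Non-saturating dose ladder in umol/g.
STUDY_DOSES = (0.0, 0.025, 0.05, 0.1, 0.15, 0.2)


# ---------------------------------------------------------------------------
# Longitudinal temperature


@dataclass
class TemperaturePhaseTemplate:
    """Triphasic daily-temperature template after an innate-immune challenge.

    Day 0 is baseline; day ``spike_day`` rises by ``spike_delta``; days in
    ``dip_days`` fall by ``dip_delta``; days in ``rebound_days`` sit at
    ``rebound_delta`` above baseline, then ramp linearly back to baseline
    by ``return_day``.  Phase windows must be ordered and non-overlapping.
    """

    baseline_c: float = 36.3
    spike_day: float = 1.0
    spike_delta: float = 0.7
    dip_days: tuple = (2.0, 4.0)
    dip_delta: float = -0.8
    rebound_days: tuple = (6.0, 14.0)
    rebound_delta: float = 0.8
    return_day: float = 28.0
    noise_sd: float = 0.3
    n_days: int = 28

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        windows = [(self.spike_day, self.spike_day), tuple(self.dip_days),
                   tuple(self.rebound_days), (self.return_day, self.return_day)]
        for (a, b), (c, d) in zip(windows, windows[1:]):
            if b < a or d < c:
                raise ValueError("phase window bounds reversed")
            if c <= b:
                raise ValueError("phase windows must be ordered and non-overlapping")

    def mean_curve(self, days: np.ndarray) -> np.ndarray:
        temps = np.full(days.shape, self.baseline_c, dtype=float)
        temps[days == self.spike_day] += self.spike_delta
        lo, hi = self.dip_days
        temps[(days >= lo) & (days <= hi)] += self.dip_delta
        lo, hi = self.rebound_days
        temps[(days >= lo) & (days <= hi)] += self.rebound_delta
        ramp = (days > hi) & (days < self.return_day)
        frac = (self.return_day - days[ramp]) / (self.return_day - hi)
        temps[ramp] += self.rebound_delta * frac
        return temps


def simulate_temperature(
    template: TemperaturePhaseTemplate,
    n_animals: int = 6,
    group: str = "MIA_polyIC",
    seed: int = 0,
) -> list[TemperatureSeries]:
    """Daily rectal-temperature series for ``n_animals`` following a template."""
    template.validate()
    rng = np.random.default_rng(seed)
    days = np.arange(0, template.n_days + 1, dtype=float)
    mean = template.mean_curve(days)
    out = []
    for i in range(n_animals):
        noise = (rng.normal(0.0, template.noise_sd, size=days.size)
                 if template.noise_sd > 0 else 0.0)
        out.append(
            TemperatureSeries(
                animal=f"{group}_{i + 1:02d}", group=group, days=days,
                temperature=mean + noise,
            )
        )
    return out


def study_mia_temperature_templates() -> dict:
    """Primed (MIA) vs control triphasic templates after poly(IC).

    MIA animals start 0.5 degC below controls (35.8 vs 36.3), share the
    day-1 rise and day-2-4 dip, and uniquely hold a +0.8 degC rebound over
    days 6-14 before returning to baseline by day 28.
    """
    mia = TemperaturePhaseTemplate(baseline_c=35.8, rebound_delta=0.8,
                                   noise_sd=0.4)
    control = TemperaturePhaseTemplate(baseline_c=36.3, rebound_delta=0.0,
                                       noise_sd=0.4)
    return {"MIA_polyIC": mia, "control_polyIC": control}


# ---------------------------------------------------------------------------
# Breath


@dataclass
class BreathSpec:
    """Recipe for canister breath tables with room-air backgrounds.

    ``background`` holds room-air mixing ratios per species (ppb; CO2 in
    ppm); ``breath_excess`` the true per-animal excess above background;
    ``group_effects`` maps group -> species -> multiplicative factor on the
    excess.  A per-animal lognormal minute-volume factor (sigma =
    ``minute_volume_cv``) scales every species' excess alike — the
    confound that CO2 normalization removes — and ``noise_cv`` adds
    per-measurement lognormal noise.
    """

    background: dict
    breath_excess: dict
    group_effects: dict
    n_per_group: int = 3
    n_background: int = 2
    timepoints: tuple = (1, 5, 10)
    minute_volume_cv: float = 0.2
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for sp, v in self.background.items():
            if v < 0:
                raise ValueError(f"background for {sp!r} must be non-negative")
        if "CO2" not in self.background:
            raise ValueError("background must include CO2")
        for sp in self.breath_excess:
            if sp not in self.background:
                raise ValueError(f"species {sp!r} has excess but no background")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def simulate_breath(spec: BreathSpec) -> pd.DataFrame:
    """Canister table: 3 timed samples per animal plus room-air backgrounds.

    Returns the layout the breathomics functions accept: columns animal,
    group, timepoint, is_background, then one column per species.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    species = sorted(spec.background)
    rows = []
    for b in range(spec.n_background):
        row = {"animal": "", "group": "room_air", "timepoint": np.nan,
               "is_background": True}
        row.update({sp: float(spec.background[sp]) for sp in species})
        rows.append(row)
    for group in sorted(spec.group_effects):
        effects = spec.group_effects[group]
        for i in range(spec.n_per_group):
            mv = (np.exp(rng.normal(0.0, spec.minute_volume_cv))
                  if spec.minute_volume_cv > 0 else 1.0)
            for t in spec.timepoints:
                row = {"animal": f"{group}_{i + 1:02d}", "group": group,
                       "timepoint": t, "is_background": False}
                for sp in species:
                    excess = spec.breath_excess.get(sp, 0.0) * effects.get(sp, 1.0)
                    noise = (np.exp(rng.normal(0.0, spec.noise_cv))
                             if spec.noise_cv > 0 else 1.0)
                    row[sp] = float(spec.background[sp] + mv * excess * noise)
                rows.append(row)
    return pd.DataFrame(rows)


def study_breath_spec(seed: int = 0) -> BreathSpec:
    """Acute-response defaults: n = 3 per group, CO / dimethylsulfide /
    methanol / methane / acetaldehyde / acetone / butyraldehyde / isoprene
    elevated after ATP, CO2 used for minute-volume normalization."""
    background = {
        "CO2": 450.0, "CO": 120.0, "methanol": 30.0, "methane": 1900.0,
        "dimethylsulfide": 2.0, "acetaldehyde": 15.0, "acetone": 25.0,
        "butyraldehyde": 1.5, "isoprene": 3.0,
    }
    breath_excess = {
        "CO2": 900.0, "CO": 60.0, "methanol": 40.0, "methane": 150.0,
        "dimethylsulfide": 3.0, "acetaldehyde": 20.0, "acetone": 40.0,
        "butyraldehyde": 2.0, "isoprene": 6.0,
    }
    atp = {"CO": 2.0, "methanol": 1.8, "methane": 1.6, "dimethylsulfide": 2.5,
           "acetaldehyde": 1.8, "acetone": 1.6, "butyraldehyde": 1.8,
           "isoprene": 2.0}
    return BreathSpec(
        background=background,
        breath_excess=breath_excess,
        group_effects={"saline": {}, "ATP": atp},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Umbrella spec


@dataclass
class PhysiologySpec:
    """Bundle of physiology generators configured to study conditions."""

    calorimetry: CalorimetrySpec = field(default_factory=study_calorimetry_spec)
    temperature_templates: dict = field(default_factory=study_mia_temperature_templates)
    temp_slopes: dict = field(default_factory=lambda: dict(STUDY_TEMP_SLOPES))
    pbrs_slopes: dict = field(default_factory=lambda: dict(STUDY_PBRS_SLOPES))
    doses: tuple = STUDY_DOSES
    seed: int = 0

    def validate(self) -> None:
        self.calorimetry.validate()
        for t in self.temperature_templates.values():
            t.validate()
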