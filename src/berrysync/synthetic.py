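"""Synthetic single-berry cohorts with the statistical structure the
pipeline assumes.

The generator emulates, per berry: double-sigmoid growth in which the
green-phase sigmoid is already completed at simulation start, so only the
ripening sigmoid is active (observation starts at softening); asynchronous
softening dates spread uniformly over a configurable window; an abrupt
arrest of net influx before the logistic asymptote (growth and phloem stop
are a fast transition) followed by slow evaporative shrivel; solute
accumulation that is strictly proportional to growth progress and stops at
the growth peak (sugar and K+), malate decay toward its arrest
concentration, and near-complete tartrate retention.  Expression data are
negative-binomial counts built from switch-off / switch-on / peak / flat
archetypes, and promoters are uniform-background sequences with motifs
planted at controlled distances from the TSS.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from the config, so identical seeds reproduce every output
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .staging import BerryTrajectory, StagingError

__all__ = [
    "CohortConfig",
    "GenotypeParams",
    "ExpressionArchetype",
    "GENOTYPES",
    "DEFAULT_ARCHETYPES",
    "simulate_growth",
    "simulate_solutes",
    "make_stage_cohort",
    "simulate_counts",
    "stage_design",
    "PromoterGroupSpec",
    "simulate_promoters",
    "pooled_sampling_artifact",
    "write_growth_tsv",
    "write_metabolites_tsv",
    "write_counts_tsv",
    "write_fasta",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CohortConfig:
    """Growth-cohort configuration.

    ``asynchrony_window`` spreads softening dates uniformly (days);
    ``growth_gain`` is the peak/softening volume ratio; ``noise_sd`` is the
    multiplicative (log-normal) SD of observed volumes.  The ripening
    sigmoid is a logistic truncated at ``arrest_fraction`` of its course,
    so the berry is still growing at finite speed when net influx stops.
    """

    n_berries: int = 12
    asynchrony_window: float = 21.0
    softening_volume: float = 1.0
    growth_gain: float = 2.0
    noise_sd: float = 0.005
    seed: int = 0
    softening_volume_cv: float = 0.15
    growth_gain_sd: float = 0.1
    ripen_duration: tuple[float, float] = (12.0, 40.0)
    shrivel_rate_mean: float = 0.002
    shrivel_rate_sigma: float = 0.6
    conc_noise_sd: float = 0.03
    logistic_k: float = 8.0
    arrest_fraction: float = 0.85
    sugar_offset: float = 0.05
    obs_margin_before: float = 7.0
    obs_margin_after: float = 21.0

    def __post_init__(self) -> None:
        if self.n_berries < 1:
            raise ConfigError("n_berries must be >= 1")
        if self.asynchrony_window < 0:
            raise ConfigError("asynchrony_window must be >= 0")
        if self.growth_gain <= 1:
            raise ConfigError("growth_gain must exceed 1")
        if self.softening_volume <= 0:
            raise ConfigError("softening_volume must be positive")
        if self.noise_sd < 0 or self.conc_noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")


@dataclass(frozen=True)
class GenotypeParams:
    """Genotype-level solute parameters.

    Concentrations: sugar in mol/L (glucose+fructose at arrest), organic
    acids in mEq/L.  ``k_flux_ratio`` is the molar sugar:K+ flux ratio
    (sugar flux / K+ flux).  ``pericarp_mass_at_arrest`` (g) is the
    reference for normalising per-fruit amounts to 1 g of pericarp.
    """

    name: str
    sugar_plateau: float
    malate_at_arrest: float
    malate_initial: float
    tartrate_retention: float
    k_flux_ratio: float
    pericarp_mass_at_arrest: float
    tartrate_initial: float = 150.0
    softening_volume: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sugar_plateau", "malate_at_arrest", "malate_initial",
                     "k_flux_ratio", "pericarp_mass_at_arrest", "tartrate_initial"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.tartrate_retention <= 1:
            raise ConfigError("tartrate_retention must be in (0, 1]")


#: Genotype presets: Syrah arrests at ~1.2 M sugar with 39 mEq/L malate;
#: the two microvines at ~0.8 M with 48 and 93 mEq/L, with a sugar:K+
#: molar flux ratio of ~30 (Syrah) and ~15 (microvines).
GENOTYPES: dict[str, GenotypeParams] = {
    "syrah": GenotypeParams("syrah", 1.2, 39.0, 390.0, 0.95, 30.0, 2.0,
                            softening_volume=1.0),
    "mv032": GenotypeParams("mv032", 0.8, 48.0, 480.0, 0.95, 15.0, 1.0,
                            softening_volume=0.5),
    "mv102": GenotypeParams("mv102", 0.8, 93.0, 465.0, 0.82, 15.0, 1.0,
                            softening_volume=0.5),
}


@dataclass(frozen=True)
class ExpressionArchetype:
    """A gene expression trajectory archetype over stages G, P, S."""

    name: str
    fold_change_G_to_S: float
    baseline_cpm: float = 100.0
    dispersion: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_cpm <= 0 or self.dispersion <= 0:
            raise ConfigError("baseline_cpm and dispersion must be positive")
        if self.name not in {"switch_off", "switch_on", "peak_up", "peak_down", "flat"}:
            raise ConfigError(f"unknown archetype {self.name!r}")

    def stage_cpms(self) -> np.ndarray:
        """Expected CPM at stages (G, P, S) before genotype wobble."""
        b, f = self.baseline_cpm, self.fold_change_G_to_S
        if self.name == "flat":
            return np.array([b, b, b])
        if self.name in ("switch_off", "switch_on"):
            return b * np.array([1.0, math.sqrt(f), f])
        # peak archetypes: excursion at P, return to baseline at S
        return b * np.array([1.0, f, 1.0])


#: Default archetype mixture: mostly flat background with an 80% repressed
#: switch-off class (the dominant pattern at phloem arrest), a switch-on
#: class and small peak classes.
DEFAULT_ARCHETYPES: dict[str, tuple[ExpressionArchetype, float]] = {
    "flat": (ExpressionArchetype("flat", 1.0), 0.60),
    "switch_off": (ExpressionArchetype("switch_off", 0.2), 0.15),
    "switch_on": (ExpressionArchetype("switch_on", 4.0), 0.15),
    "peak_up": (ExpressionArchetype("peak_up", 3.0), 0.05),
    "peak_down": (ExpressionArchetype("peak_down", 0.33), 0.05),
}


# ---------------------------------------------------------------------------
# growth model


@dataclass(frozen=True)
class BerryModel:
    """Noiseless per-berry growth/solute kinetics (hidden simulation truth)."""

    softening_day: float
    softening_volume: float
    gain: float
    ripen_days: float
    shrivel_rate: float
    logistic_k: float
    arrest_fraction: float

    @property
    def peak_day(self) -> float:
        return self.softening_day + self.arrest_fraction * self.ripen_days

    @property
    def peak_volume(self) -> float:
        return self.softening_volume * self.gain

    def progress(self, day) -> np.ndarray:
        """Normalised ripening progress in [0, 1]; 1 from the peak onward."""
        day = np.asarray(day, dtype=float)
        u = np.clip((day - self.softening_day) / self.ripen_days, 0.0, self.arrest_fraction)
        k = self.logistic_k
        sig = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
        s0 = sig(-0.5 * k)
        s_arr = sig(k * (self.arrest_fraction - 0.5))
        return (sig(k * (u - 0.5)) - s0) / (s_arr - s0)

    def relative_volume(self, day) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        grow = 1.0 + (self.gain - 1.0) * self.progress(day)
        past = day > self.peak_day
        shrivel = self.gain * np.exp(-self.shrivel_rate * np.maximum(day - self.peak_day, 0.0))
        return np.where(past, shrivel, grow)

    def volume(self, day) -> np.ndarray:
        return self.softening_volume * self.relative_volume(day)


def _picture_grid(start: float, stop: float) -> np.ndarray:
    """Global twice-weekly picture days (0, 3, 7, 10, 14, ...)."""
    k_max = int(stop // 7 + 2) * 2
    days = np.array([7 * (k // 2) + 3 * (k % 2) for k in range(k_max + 2)], dtype=float)
    return days[(days >= start) & (days <= stop)]


def simulate_growth(config: CohortConfig, seed: int | None = None) -> list[BerryTrajectory]:
    """Simulate a cohort of berry growth trajectories.

    Observed volumes carry multiplicative log-normal noise of SD
    ``config.noise_sd``; the noiseless model is attached to each
    trajectory as ``meta["model"]`` (the simulation truth).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.ripen_duration
    berries = []
    for i in range(config.n_berries):
        soften = float(rng.uniform(0.0, config.asynchrony_window)) if config.asynchrony_window > 0 else 0.0
        cv = config.softening_volume_cv
        vs = config.softening_volume * float(rng.lognormal(-0.5 * math.log(1 + cv**2),
                                                           math.sqrt(math.log(1 + cv**2)))) if cv > 0 else config.softening_volume
        gain = max(1.2, float(rng.normal(config.growth_gain, config.growth_gain_sd)))
        ripen = float(rng.uniform(lo, hi))
        sigma = config.shrivel_rate_sigma
        shrivel = float(rng.lognormal(math.log(config.shrivel_rate_mean) - 0.5 * sigma**2, sigma)) \
            if config.shrivel_rate_mean > 0 else 0.0
        model = BerryModel(soften, vs, gain, ripen, shrivel,
                           config.logistic_k, config.arrest_fraction)
        days = _picture_grid(max(0.0, soften - config.obs_margin_before),
                             soften + ripen + config.obs_margin_after)
        vol = model.volume(days)
        if config.noise_sd > 0:
            vol = vol * np.exp(rng.normal(0.0, config.noise_sd, size=days.size))
        traj = BerryTrajectory(
            berry_id=f"b{i:03d}",
            days=days,
            volume=vol,
            softening_day=soften,
            meta={"model": model},
        )
        berries.append(traj)
    return berries


# ---------------------------------------------------------------------------
# solutes


def _solute_truth(model: BerryModel, params: GenotypeParams, days: np.ndarray,
                  sugar_offset: float) -> pd.DataFrame:
    """Noiseless per-fruit amounts (mmol / mEq) at the given days."""
    p = model.progress(days)
    vol = model.volume(days)
    # mol/L x mL = mmol; mEq/L x mL / 1000 = mEq
    q_max = params.sugar_plateau * model.peak_volume  # mmol glucose+fructose at arrest
    sugar = q_max * (sugar_offset + (1.0 - sugar_offset) * p)
    k_base = q_max / (2.0 * params.k_flux_ratio)
    potassium = k_base + sugar / params.k_flux_ratio  # mEq (monovalent: mEq = mmol)
    # malate concentration interpolates geometrically initial -> arrest,
    # then the remaining amount is still oxidised at a low rate
    c_mal = params.malate_initial * (params.malate_at_arrest / params.malate_initial) ** p
    past = np.maximum(days - model.peak_day, 0.0)
    malate = c_mal * vol / 1000.0 * np.exp(-0.01 * past)
    tart0 = params.tartrate_initial * model.softening_volume / 1000.0  # mEq
    tartrate = tart0 * (1.0 - (1.0 - params.tartrate_retention) * p)
    return pd.DataFrame(
        {
            "day": days,
            "true_volume_ml": vol,
            "true_sugar_mmol": sugar,
            "true_potassium_meq": potassium,
            "true_malate_meq": malate,
            "true_tartrate_meq": tartrate,
        }
    )


def simulate_solutes(
    traj: BerryTrajectory,
    params: GenotypeParams,
    seed: int = 0,
    conc_noise_sd: float = 0.03,
    days: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-berry metabolite/ion time series with measurement noise.

    Concentrations (glucose/fructose mol/L, acids and K+ mEq/L) carry
    additive Gaussian noise with SD proportional to the value; measured
    volume is the trajectory's (noisy) volume.  Per-fruit amounts are
    consistent: amount = concentration x measured volume.
    """
    model: BerryModel | None = traj.meta.get("model")
    if model is None:
        raise StagingError("simulate_solutes needs a synthetic trajectory (no growth model)")
    rng = np.random.default_rng(seed)
    if days is None:
        days = traj.days
        meas_vol = traj.volume.copy()
    else:
        days = np.asarray(days, dtype=float)
        meas_vol = model.volume(days)
    truth = _solute_truth(model, params, days, sugar_offset=0.05)
    # amounts -> concentrations over the true volume, then noise
    vol = truth["true_volume_ml"].to_numpy()
    sugar_mmol = truth["true_sugar_mmol"].to_numpy()
    conc = {
        "glucose_mol_l": 0.5 * sugar_mmol / vol,
        "fructose_mol_l": 0.5 * sugar_mmol / vol,
        "malate_meq_l": truth["true_malate_meq"].to_numpy() * 1000.0 / vol,
        "tartrate_meq_l": truth["true_tartrate_meq"].to_numpy() * 1000.0 / vol,
        "potassium_meq_l": truth["true_potassium_meq"].to_numpy() * 1000.0 / vol,
    }
    out = {"berry_id": traj.berry_id, "day": days}
    for name, values in conc.items():
        noisy = values + rng.normal(0.0, conc_noise_sd, size=values.size) * values \
            if conc_noise_sd > 0 else values
        out[name] = np.maximum(noisy, 0.0)
    out["volume_ml"] = meas_vol
    out["fresh_mass_g"] = meas_vol * 1.0  # 1 mL ~= 1 g
    frame = pd.DataFrame(out)
    return pd.concat([frame, truth.drop(columns="day")], axis=1)


# ---------------------------------------------------------------------------
# stage-design cohort (the study's sampling scheme)


@dataclass
class StageCohort:
    """A per-genotype stage-sampled cohort: trajectories + sampled panel."""

    genotype: str
    trajectories: list[BerryTrajectory]
    panel: pd.DataFrame  # one row per sampled berry
    sampling_days: dict[str, float]
    truth: pd.DataFrame


def make_stage_cohort(
    config: CohortConfig,
    params: GenotypeParams,
    n_per_stage: int = 3,
    seed: int | None = None,
) -> StageCohort:
    """Simulate a cohort and select ``n_per_stage`` berries per stage.

    Mirrors the study protocol, in which stages were judged from the same
    pictures the staging module analyses: berries are *selected* from the
    monitored population on their observed growth — the fastest-growing
    berries for G (sampled when the observed profile crosses half its
    ripening gain), berries at their observed (median-smoothed) day of
    maximum volume for P, and berries 14 d past that day for S.  Because
    the observed maximum lags the true arrest by up to one picture
    interval, P berries are typically sampled just after the true arrest.
    The truth table keeps each berry's true softening/arrest days for
    audit.
    """
    from .staging import detect_peak, normalize_growth

    base_seed = config.seed if seed is None else seed
    if config.n_berries < 3 * n_per_stage:
        config = replace(config, n_berries=3 * n_per_stage + 3)
    config = replace(config, softening_volume=params.softening_volume)
    trajs = simulate_growth(config, seed=base_seed)
    rng = np.random.default_rng(base_seed + 1)
    for t in trajs:
        normalize_growth(t)
        detect_peak(t, smoother="median3")

    # observed relative gain within 14 d of softening ("growing at full speed")
    def obs_gain14(t: BerryTrajectory) -> float:
        return t.relative_volume_at(t.softening_day + 14.0) - 1.0

    usable = [t for t in trajs if t.peak_reached]
    # G berries must still be growing at the 14-d probe: observed peak
    # comfortably after it (fast but not yet arrested)
    eligible = [t for t in usable if t.peak_day - t.softening_day >= 18.0]
    if len(eligible) < n_per_stage:
        extra = sorted((t for t in usable if t not in eligible),
                       key=lambda t: t.peak_day - t.softening_day, reverse=True)
        eligible += extra[: n_per_stage - len(eligible)]
    order = sorted(eligible, key=obs_gain14, reverse=True)
    g_berries = order[:n_per_stage]
    rest = [t for t in usable if t not in g_berries]
    rng.shuffle(rest)
    p_berries = rest[:n_per_stage]
    s_berries = rest[n_per_stage:2 * n_per_stage]
    if len(s_berries) < n_per_stage:
        raise ConfigError("not enough berries for the requested stage design")

    sampling_days: dict[str, float] = {}
    stages: dict[str, str] = {}
    for t in g_berries:
        # earliest grid day at which the observed profile crossed half its
        # observed ripening gain, kept clear of the V and P windows
        obs_gain = t.relative_volume[np.searchsorted(t.days, t.peak_day)] - 1.0
        target = 1.0 + 0.5 * obs_gain
        inside = (t.days > t.softening_day + 2.5) & (t.days < t.peak_day - 3.5)
        candidates = t.days[inside & (t.relative_volume >= target)]
        day = float(candidates[0]) if candidates.size else float(t.days[inside][-1])
        sampling_days[t.berry_id] = day
        stages[t.berry_id] = "G"
    for t in p_berries:
        sampling_days[t.berry_id] = float(t.peak_day)
        stages[t.berry_id] = "P"
    for t in s_berries:
        later = t.days[t.days >= t.peak_day + 14.0]
        sampling_days[t.berry_id] = float(later[0]) if later.size else float(t.days[-1])
        stages[t.berry_id] = "S"

    rows = []
    sampled = g_berries + p_berries + s_berries
    for j, t in enumerate(sampled):
        m = t.meta["model"]
        day = sampling_days[t.berry_id]
        series = simulate_solutes(t, params, seed=base_seed + 100 + j,
                                  conc_noise_sd=config.conc_noise_sd,
                                  days=np.array([day]))
        row = series.iloc[0].to_dict()
        # measured volume at the sampling day (with observation noise)
        row["volume_ml"] = t.volume_at(day)
        row["fresh_mass_g"] = row["volume_ml"]
        row.update(
            genotype=params.name,
            stage=stages[t.berry_id],
            arrest_mass_g=m.peak_volume * 1.0,
        )
        rows.append(row)
    panel = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "berry_id": [t.berry_id for t in sampled],
            "stage": [stages[t.berry_id] for t in sampled],
            "sampling_day": [sampling_days[t.berry_id] for t in sampled],
            "true_peak_day": [t.meta["model"].peak_day for t in sampled],
            "true_softening_day": [t.meta["model"].softening_day for t in sampled],
        }
    )
    return StageCohort(params.name, trajs, panel, sampling_days, truth)


# ---------------------------------------------------------------------------
# counts


def stage_design(genotypes=("syrah", "mv032", "mv102"), stages=("G", "P", "S"),
                 n_reps: int = 3) -> pd.DataFrame:
    """Sample sheet for a stage x genotype x replicate layout."""
    rows = [
        {"sample_id": f"{g}-{s}-{r + 1}", "genotype": g, "stage": s, "replicate": r + 1}
        for g in genotypes for s in stages for r in range(n_reps)
    ]
    return pd.DataFrame(rows)


def simulate_counts(
    design: pd.DataFrame,
    archetypes: dict | None = None,
    n_genes: int = 2000,
    library_size: float = 1e6,
    seed: int = 0,
    genotype_sd: float = 0.1,
    library_cv: float = 0.15,
    baseline_log_mean: float = 3.0,
    baseline_log_sd: float = 1.5,
):
    """Negative-binomial count matrix plus a truth table.

    Stage means follow each archetype's (G, P, S) CPM profile with a mild
    per-gene x genotype log-normal wobble.  Flat background genes are
    rescaled per sample so expected CPMs total 1e6.  Returns
    ``(counts, gene_lengths, truth)``.
    """
    if design["stage"].nunique() < 2:
        raise ConfigError("need >=2 stages")
    if library_size <= 0:
        raise ConfigError("library size must be positive")
    archetypes = archetypes or DEFAULT_ARCHETYPES
    rng = np.random.default_rng(seed)

    names, weights, protos = [], [], []
    for name, (proto, w) in archetypes.items():
        names.append(name)
        weights.append(w)
        protos.append(proto)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    assignment = rng.choice(len(names), size=n_genes, p=weights)

    gene_ids = np.array([f"gene{i:05d}" for i in range(n_genes)])
    stage_idx = {"G": 0, "P": 1, "S": 2}
    genotypes = sorted(design["genotype"].unique())

    base = np.empty(n_genes)
    disp = np.empty(n_genes)
    fold = np.empty(n_genes)
    profile = np.empty((n_genes, 3))
    for gi in range(n_genes):
        proto = protos[assignment[gi]]
        if proto.name == "flat":
            # flat background redrawn from the genome-wide abundance law
            b = float(rng.lognormal(baseline_log_mean, baseline_log_sd))
        else:
            # mean-one jitter keeps the planted baseline CPM exact on average
            b = proto.baseline_cpm * float(rng.lognormal(-0.125, 0.5))
        arch = ExpressionArchetype(proto.name, proto.fold_change_G_to_S, b, proto.dispersion)
        base[gi] = b
        disp[gi] = proto.dispersion
        fold[gi] = proto.fold_change_G_to_S
        profile[gi] = arch.stage_cpms()

    wobble = {g: rng.lognormal(0.0, genotype_sd, size=n_genes) for g in genotypes}

    flat_mask = np.array([names[a] == "flat" for a in assignment])
    counts = np.empty((n_genes, len(design)), dtype=np.int64)
    libs = library_size * np.exp(rng.normal(0.0, library_cv, size=len(design))) \
        if library_cv > 0 else np.full(len(design), library_size)
    for si, row in enumerate(design.itertuples(index=False)):
        cpm = profile[:, stage_idx[row.stage]] * wobble[row.genotype]
        flat_total = cpm[flat_mask].sum() if flat_mask.any() else 0.0
        if flat_total > 0:
            non_flat = cpm[~flat_mask].sum()
            target = max(1e6 - non_flat, 0.2 * flat_total)
            cpm = cpm.copy()
            cpm[flat_mask] *= target / flat_total
        mu = cpm * libs[si] / 1e6
        lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
        counts[:, si] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design["sample_id"].to_numpy())
    lengths = pd.Series(
        np.round(np.exp(rng.normal(math.log(1500.0), 0.4, size=n_genes))).astype(int),
        index=gene_ids, name="length_bp",
    ).clip(lower=200)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "archetype": [names[a] for a in assignment],
            "baseline_cpm": base,
            "fold_change_G_to_S": np.where(flat_mask, 1.0,
                                           np.where([names[a].startswith("peak") for a in assignment],
                                                    1.0, fold)),
            "dispersion": disp,
        }
    ).set_index("gene_id")
    return counts_df, lengths, truth


# ---------------------------------------------------------------------------
# promoters


@dataclass(frozen=True)
class PromoterGroupSpec:
    """A co-regulated gene group with motifs planted near the TSS.

    ``center``/``jitter``: planted sites have their TSS-proximal end at a
    distance uniform on [center - jitter, center + jitter] from the TSS.
    """

    name: str
    genes: tuple
    motifs: tuple
    center: int = 50
    jitter: int = 20


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _resolve_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in "ACGT" else _IUPAC[c][rng.integers(len(_IUPAC[c]))] for c in consensus
    )


@dataclass
class SimulatedPromoters:
    """Synthetic genome + dual annotations for the CRE module."""

    genome: dict  # contig -> sequence
    annotation_a: pd.DataFrame  # gene_id, contig, strand, start, end (1-based)
    annotation_b: pd.DataFrame
    truth: pd.DataFrame  # planted sites: gene_id, motif_id, offset, strand

    def gff_text(self, which: str = "a") -> str:
        ann = self.annotation_a if which == "a" else self.annotation_b
        lines = ["##gff-version 3"]
        for row in ann.itertuples(index=False):
            lines.append(
                f"{row.contig}\tberrysync\tgene\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t"
                f"ID={row.gene_id};Name={row.gene_id}"
            )
        return "\n".join(lines) + "\n"


def simulate_promoters(
    gene_groups,
    motif_library: dict,
    promoter_length: int = 1500,
    seed: int = 0,
    gene_body: int = 500,
    margin: int = 100,
    tss_shift: int = 100,
) -> SimulatedPromoters:
    """Plant group motifs into uniform-background promoters.

    One contig per gene.  Genes alternate strands.  Two annotations are
    produced: variant A with the true TSS and variant B with the TSS
    shifted ``tss_shift`` nt into the gene (a lost 5'UTR), exercising the
    longest-transcript TSS-selection rule downstream.
    """
    for m_id, consensus in motif_library.items():
        bad = set(consensus) - set(_IUPAC)
        if bad:
            raise ValueError(f"motif {m_id}: invalid IUPAC codes {sorted(bad)}")
        if len(consensus) >= promoter_length:
            raise ValueError(f"motif {m_id} is not shorter than the promoter")
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    rows_a, rows_b, truth_rows = [], [], []
    alphabet = np.array(list("ACGT"))

    planted: dict[str, list[tuple[str, int, str]]] = {}
    for group in gene_groups:
        for gene in group.genes:
            planted.setdefault(gene, [])
            taken: list[tuple[int, int]] = []
            for motif_id in group.motifs:
                consensus = motif_library[motif_id]
                L = len(consensus)
                for _ in range(100):
                    offset = int(rng.integers(max(group.center - group.jitter, 0),
                                              group.center + group.jitter + 1))
                    start = promoter_length - offset - L  # oriented coords
                    if start < 0:
                        continue
                    if all(start + L <= s or start >= s + sl for s, sl in taken):
                        taken.append((start, L))
                        break
                else:
                    raise ValueError("could not place motif without overlap")
                strand = "+" if rng.random() < 0.5 else "-"
                planted[gene].append((motif_id, offset, strand))

    all_genes: list[str] = []
    for group in gene_groups:
        for g in group.genes:
            if g not in all_genes:
                all_genes.append(g)

    contig_len = margin + promoter_length + gene_body + margin
    for idx, gene in enumerate(all_genes):
        seq = rng.choice(alphabet, size=contig_len)
        strand = "+" if idx % 2 == 0 else "-"
        if strand == "+":
            tss = margin + promoter_length + 1  # 1-based
            start, end = tss, tss + gene_body - 1
            # oriented promoter = genomic [tss-1500, tss-1] left->right
            def place(oriented_start: int, inst: str) -> None:
                g0 = margin + oriented_start  # 0-based genomic
                seq[g0:g0 + len(inst)] = list(inst)
        else:
            start, end = margin + 1, margin + gene_body
            tss = end
            # oriented promoter position i maps to genomic base tss+ (P - i),
            # reverse-complemented
            def place(oriented_start: int, inst: str) -> None:
                rc = reverse_complement(inst)
                g_end = tss + (promoter_length - oriented_start)  # 1-based inclusive
                g0 = g_end - len(inst)  # 0-based start
                seq[g0:g0 + len(inst)] = list(rc)
        for motif_id, offset, mstrand in planted.get(gene, []):
            consensus = motif_library[motif_id]
            inst = _resolve_iupac(consensus, rng)
            if mstrand == "-":
                inst = reverse_complement(inst)
            oriented_start = promoter_length - offset - len(consensus)
            place(oriented_start, inst)
            truth_rows.append(
                {"gene_id": gene, "motif_id": motif_id, "offset": offset, "strand": mstrand}
            )
        contig = f"ctg_{gene}"
        genome[contig] = "".join(seq)
        rows_a.append({"gene_id": gene, "contig": contig, "strand": strand,
                       "start": start, "end": end})
        if strand == "+":
            rows_b.append({"gene_id": gene, "contig": contig, "strand": strand,
                           "start": start + tss_shift, "end": end})
        else:
            rows_b.append({"gene_id": gene, "contig": contig, "strand": strand,
                           "start": start, "end": end - tss_shift})
    return SimulatedPromoters(
        genome=genome,
        annotation_a=pd.DataFrame(rows_a),
        annotation_b=pd.DataFrame(rows_b),
        truth=pd.DataFrame(truth_rows, columns=["gene_id", "motif_id", "offset", "strand"]),
    )


# ---------------------------------------------------------------------------
# the averaging artefact


@dataclass
class ArtefactReport:
    """Calendar-pooled vs per-berry synchronised solute accounting."""

    days: np.ndarray
    pooled_volume: np.ndarray
    pooled_sugar: np.ndarray
    pooled_volume_peak_day: float
    sugar_rising_days_after_peak: float
    pooled_post_peak_sugar_slope: float
    sync_offsets: np.ndarray
    sync_sugar: np.ndarray
    per_berry_post_peak_slope_mean: float
    per_berry_post_peak_slope_p: float
    artefact_detected: bool


def pooled_sampling_artifact(
    trajectories,
    params: GenotypeParams,
    seed: int = 0,
    conc_noise_sd: float = 0.03,
    min_rise_days: float = 7.0,
) -> ArtefactReport:
    """Contrast calendar-date pooling with per-berry synchronisation.

    Pooled series average the (noiseless) model curves of all berries on a
    common daily grid — the classical asynchronous-sample analysis.  The
    synchronised series re-align each berry on its own growth peak.  The
    artefact is declared when the pooled mean sugar amount keeps rising
    for >= ``min_rise_days`` after the pooled mean volume peak while the
    per-berry post-peak slope is statistically indistinguishable from 0.
    """
    from scipy import stats

    models = [t.meta["model"] for t in trajectories]
    if not models:
        raise ValueError("empty cohort")
    t0 = min(m.softening_day for m in models) - 2.0
    t1 = max(m.softening_day + m.ripen_days for m in models) + 21.0
    days = np.arange(t0, t1 + 1.0)

    vol = np.mean([m.volume(days) for m in models], axis=0)
    sugars = []
    for m in models:
        p = m.progress(days)
        q_max = params.sugar_plateau * m.peak_volume
        sugars.append(q_max * (0.05 + 0.95 * p))
    sugar = np.mean(sugars, axis=0)

    peak_idx = int(np.argmax(vol))
    peak_day = float(days[peak_idx])
    rising = np.flatnonzero(np.diff(sugar) > 1e-9 * max(sugar.max(), 1.0))
    last_rise_day = float(days[rising[-1] + 1]) if rising.size else float(days[0])
    rise_after = max(0.0, last_rise_day - peak_day)

    # pooled slope over the week after the pooled volume peak (mmol/day)
    win = (days >= peak_day) & (days <= peak_day + max(min_rise_days, 1.0))
    pooled_slope = float(np.polyfit(days[win], sugar[win], 1)[0]) if win.sum() >= 2 else 0.0

    # synchronised: noisy sampled amounts at each berry's own peak + offsets
    rng = np.random.default_rng(seed)
    offsets = np.arange(0.0, 15.0, 3.5)
    slopes = []
    sync = []
    for m in models:
        p = m.progress(m.peak_day + offsets)
        q = params.sugar_plateau * m.peak_volume * (0.05 + 0.95 * p)
        if conc_noise_sd > 0:
            q = q * (1.0 + rng.normal(0.0, conc_noise_sd, size=q.size))
        sync.append(q)
        slopes.append(float(np.polyfit(offsets, q, 1)[0]))
    slopes = np.asarray(slopes)
    sync = np.asarray(sync)
    if len(models) > 1 and np.std(slopes) > 0:
        _, p_val = stats.ttest_1samp(slopes, 0.0)
    else:
        p_val = 1.0
    # per-berry slopes count as indistinguishable from 0 when the t-test
    # does not reject at 1% or their mean is negligible against the pooled
    # post-peak rise (the t-test alone over-rejects at large n)
    flat_per_berry = p_val > 0.01 or (
        pooled_slope > 0 and abs(float(np.mean(slopes))) <= 0.05 * pooled_slope)
    detected = rise_after >= min_rise_days and pooled_slope > 0 and flat_per_berry
    return ArtefactReport(
        days=days,
        pooled_volume=vol,
        pooled_sugar=sugar,
        pooled_volume_peak_day=peak_day,
        sugar_rising_days_after_peak=rise_after,
        pooled_post_peak_sugar_slope=pooled_slope,
        sync_offsets=offsets,
        sync_sugar=sync,
        per_berry_post_peak_slope_mean=float(np.mean(slopes)),
        per_berry_post_peak_slope_p=float(p_val),
        artefact_detected=bool(detected),
    )


# ---------------------------------------------------------------------------
# writers (plain-text outputs)

_BASE_DATE = pd.Timestamp("2021-08-01")


def write_growth_tsv(trajectories, path, softening_out: dict | None = None) -> None:
    """Growth table: berry_id, date (ISO-8601), area_cm2, softening_date."""
    rows = []
    for t in trajectories:
        # invert the sphere-equivalent volume back to a projected area
        r = (3.0 * t.volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        area = math.pi * r**2
        for d, a in zip(t.days, area):
            rows.append(
                {
                    "berry_id": t.berry_id,
                    "date": (_BASE_DATE + pd.Timedelta(days=float(d))).date().isoformat(),
                    "area_cm2": round(float(a), 6),
                    "softening_date": (_BASE_DATE + pd.Timedelta(days=float(t.softening_day))).date().isoformat(),
                }
            )
    with open(path, "w") as fh:
        fh.write("# berrysync synthetic growth table; areas cm^2 (sphere-equivalent)\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_metabolites_tsv(panel: pd.DataFrame, path) -> None:
    cols = [c for c in panel.columns if not c.startswith("true_")]
    with open(path, "w") as fh:
        fh.write("# berrysync metabolite panel; sugars mol/L, acids and K+ mEq/L, volume mL\n")
        panel[cols].to_csv(fh, sep="\t", index=False)


def write_counts_tsv(counts: pd.DataFrame, lengths: pd.Series, counts_path, lengths_path) -> None:
    counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    lengths.rename_axis("gene_id").to_csv(lengths_path, sep="\t")


def write_fasta(genome: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
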