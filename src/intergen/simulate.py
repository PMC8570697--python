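"""Synthetic four-species intergenerational stress experiment with ground truth.

The generator emulates the statistical structure the analysis assumes:
negative-binomial counts (``Var = mu + alpha * mu**2``) over a harmonized
orthogroup universe, with a log-normal baseline-mean distribution, a
``alpha(mu) = a1/mu + a0`` dispersion trend with gene-level log-normal
noise, per-sample library-size factors, and planted per-orthogroup effect
classes:

* ``null`` — no stress effect anywhere;
* ``conserved_all`` — same-direction effect in all species, one stress;
* ``shared_both_stresses`` — same-direction effect in all species under
  both stresses;
* ``adaptive_only`` — effect confined to the species whose offspring
  phenotypically adapt to the stress;
* ``inverted`` — up in the adapting species, down in the species with
  the deleterious outcome (the rhy-1 pattern; pathogen stress only, the
  only stress with a deleterious-phenotype species);
* ``single_species`` — effect in exactly one species, one stress.

A configurable fraction of orthogroups is made multi-copy in exactly one
species, with the extra paralog either silent (rescue-positive) or
expressed (rescue-negative), to exercise the expression-based rescue
rule.  F1 effects persist into F3 samples for a configurable fraction of
affected orthogroups (default 0: intergenerational only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .crossspecies import PhenotypeMap, default_phenotype_map
from .io import (
    CountMatrix,
    DEFAULT_SPECIES,
    DEFAULT_STRESSES,
    OrthogroupTable,
    SampleSheet,
)
from .timing import EmbryoTimecourse

SPECIES_CODES = {
    "C. elegans": "cel",
    "C. briggsae": "cbr",
    "C. kamaaina": "cka",
    "C. tropicalis": "ctr",
}

_DEFAULT_PROPORTIONS = {
    "null": 0.85,
    "conserved_all": 0.03,
    "adaptive_only": 0.03,
    "inverted": 0.02,
    "single_species": 0.04,
    "shared_both_stresses": 0.03,
}


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Baseline means are log-normal on the count scale (median
    ``baseline_median``, spread ``baseline_sdlog`` in natural-log units);
    dispersions follow ``a1/mu + a0`` times log-normal gene noise;
    library-size factors are uniform on a log range; planted |log2
    effect| is uniform on ``effect_log2_range`` with random sign unless
    the class dictates the sign pattern.
    """

    n_orthogroups: int = 8000
    species: tuple[str, ...] = DEFAULT_SPECIES
    stresses: tuple[str, ...] = DEFAULT_STRESSES
    replicates: int = 3
    baseline_median: float = 100.0
    baseline_sdlog: float = 1.0
    baseline_species_jitter_sdlog: float = 0.3
    dispersion_a0: float = 0.01
    dispersion_a1: float = 1.0
    dispersion_noise_sdlog: float = 0.3
    libsize_range: tuple[float, float] = (0.5, 2.0)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    effect_log2_range: tuple[float, float] = (1.5, 3.0)
    rescue_positive_fraction: float = 0.05
    rescue_negative_fraction: float = 0.02
    f3_persistence_fraction: float = 0.0
    timing_outside_fraction: float = 0.5
    n_timepoints: int = 12
    time_range_minutes: tuple[float, float] = (0.0, 750.0)

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class proportions must sum to 1 (got {total!r})"
            )
        for name, frac in (
            ("rescue_positive_fraction", self.rescue_positive_fraction),
            ("rescue_negative_fraction", self.rescue_negative_fraction),
            ("f3_persistence_fraction", self.f3_persistence_fraction),
            ("timing_outside_fraction", self.timing_outside_fraction),
            *((f"proportion[{k}]", v) for k, v in self.class_proportions.items()),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {frac}")
        if self.replicates < 2:
            raise ConfigurationError("need at least 2 replicates per condition")
        if self.libsize_range[0] <= 0 or self.libsize_range[0] > self.libsize_range[1]:
            raise ConfigurationError("invalid library-size factor range")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for parameter recovery."""

    classes: pd.Series  # og_id -> effect class
    effects_f1: dict[tuple[str, str], pd.Series]  # (species, stress) -> log2 effect
    effects_f3: dict[tuple[str, str], pd.Series]
    rescue_status: pd.Series  # og_id -> none | rescue_positive | rescue_negative
    representatives: dict[str, pd.Series]  # species -> og_id -> expressed gene id
    baselines: dict[str, pd.Series]  # species -> gene id -> baseline mean
    dispersions: dict[str, pd.Series]  # species -> gene id -> alpha
    library_factors: pd.Series  # sample_id -> factor
    timing_outside: pd.Series | None = None  # cel gene -> planted outside-range flag


@dataclass
class SyntheticExperiment:
    counts: dict[str, CountMatrix]
    sheet: SampleSheet
    orthogroups: OrthogroupTable
    phenotypes: PhenotypeMap
    truth: SyntheticTruth


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws with Var = mu + alpha*mu^2 (Poisson when alpha ~ 0)."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    tiny = alpha < 1e-8
    pois = pos & tiny
    nb = pos & ~tiny
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def _plant_effects(
    config: SyntheticConfig,
    rng: np.random.Generator,
    og_ids: list[str],
    classes: pd.Series,
    phenotypes: PhenotypeMap,
) -> dict[tuple[str, str], pd.Series]:
    species, stresses = config.species, config.stresses
    lo, hi = config.effect_log2_range
    effects = {
        (sp, st): pd.Series(0.0, index=og_ids) for sp in species for st in stresses
    }
    inverted_stresses = [st for st in stresses if phenotypes.contrast_species(st)]
    for og in og_ids:
        cls = classes[og]
        if cls == "null":
            continue
        mag = rng.uniform(lo, hi)
        sign = rng.choice([-1.0, 1.0])
        if cls == "conserved_all":
            st = stresses[rng.integers(len(stresses))]
            for sp in species:
                effects[(sp, st)][og] = sign * mag
        elif cls == "shared_both_stresses":
            for st in stresses:
                for sp in species:
                    effects[(sp, st)][og] = sign * mag
        elif cls == "adaptive_only":
            st = stresses[rng.integers(len(stresses))]
            for sp in phenotypes.include_species(st):
                effects[(sp, st)][og] = sign * mag
        elif cls == "inverted":
            st = inverted_stresses[rng.integers(len(inverted_stresses))]
            for sp in phenotypes.include_species(st):
                effects[(sp, st)][og] = mag
            for sp in phenotypes.contrast_species(st):
                effects[(sp, st)][og] = -mag
        elif cls == "single_species":
            st = stresses[rng.integers(len(stresses))]
            sp = species[rng.integers(len(species))]
            effects[(sp, st)][og] = sign * mag
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown effect class {cls!r}")
    return effects


def generate_experiment(config: SyntheticConfig, seed: int) -> SyntheticExperiment:
    """Draw the full four-species F1/F3 experiment with planted truth.

    Per species the sample grid is (F1, F3) x (control + one condition
    per stress) x replicates; counts for a stress condition carry that
    stress's planted log2 effect (F1 always; F3 only for persistent
    orthogroups).  The orthogroup table contains the planted single-copy
    and multi-copy structures.
    """
    rng = np.random.default_rng(seed)
    species = list(config.species)
    stresses = list(config.stresses)
    n = config.n_orthogroups
    og_ids = [f"OG{i:06d}" for i in range(1, n + 1)]
    phenotypes = default_phenotype_map()

    labels = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in labels])
    classes = pd.Series(rng.choice(labels, size=n, p=probs), index=og_ids)

    effects_f1 = _plant_effects(config, rng, og_ids, classes, phenotypes)
    persists = pd.Series(False, index=og_ids)
    if config.f3_persistence_fraction > 0:
        affected = classes.index[classes != "null"]
        persists[affected] = (
            rng.random(len(affected)) < config.f3_persistence_fraction
        )
    effects_f3 = {
        key: eff.where(persists, 0.0) for key, eff in effects_f1.items()
    }

    # rescue structure: multi-copy in exactly one (random) species
    n_pos = int(round(config.rescue_positive_fraction * n))
    n_neg = int(round(config.rescue_negative_fraction * n))
    shuffled = rng.permutation(n)
    pos_idx = set(shuffled[:n_pos])
    neg_idx = set(shuffled[n_pos:n_pos + n_neg])
    rescue_status = pd.Series("none", index=og_ids)
    multi_species = pd.Series("", index=og_ids)
    for i, og in enumerate(og_ids):
        if i in pos_idx or i in neg_idx:
            rescue_status[og] = "rescue_positive" if i in pos_idx else "rescue_negative"
            multi_species[og] = species[rng.integers(len(species))]

    # shared per-orthogroup baseline, jittered per species
    base_og = config.baseline_median * np.exp(
        rng.normal(0.0, config.baseline_sdlog, size=n)
    )

    entries: dict[str, dict[str, list[str]]] = {og: {} for og in og_ids}
    baselines: dict[str, pd.Series] = {}
    dispersions: dict[str, pd.Series] = {}
    representatives: dict[str, pd.Series] = {}
    gene_meta: dict[str, tuple[list[str], np.ndarray, np.ndarray, np.ndarray]] = {}

    for sp in species:
        code = SPECIES_CODES.get(sp, sp.replace(" ", "_").replace(".", ""))
        genes: list[str] = []
        mus: list[float] = []
        og_of_gene: list[str] = []
        is_rep: list[bool] = []
        jitter = np.exp(rng.normal(0.0, config.baseline_species_jitter_sdlog, size=n))
        rep_map = {}
        for i, og in enumerate(og_ids):
            g = f"{code}_{og}"
            members = [g]
            genes.append(g)
            mus.append(base_og[i] * jitter[i])
            og_of_gene.append(og)
            is_rep.append(True)
            if rescue_status[og] != "none" and multi_species[og] == sp:
                g2 = f"{code}_{og}_p2"
                members.append(g2)
                genes.append(g2)
                if rescue_status[og] == "rescue_positive":
                    mus.append(0.0)  # silent paralog: zero in every sample
                else:
                    mus.append(max(20.0, base_og[i] * 0.5))  # expressed paralog
                og_of_gene.append(og)
                is_rep.append(False)
            entries[og][sp] = members
            rep_map[og] = g
        mus_arr = np.array(mus)
        with np.errstate(divide="ignore"):
            trend = np.where(
                mus_arr > 0,
                config.dispersion_a1 / np.maximum(mus_arr, 1e-300) + config.dispersion_a0,
                config.dispersion_a0,
            )
        alphas = trend * np.exp(
            rng.normal(0.0, config.dispersion_noise_sdlog, size=len(mus_arr))
        )
        baselines[sp] = pd.Series(mus_arr, index=genes)
        dispersions[sp] = pd.Series(alphas, index=genes)
        representatives[sp] = pd.Series(rep_map)
        gene_meta[sp] = (genes, mus_arr, alphas, np.array(og_of_gene))

    # sample grid and counts
    conditions = ["control", *stresses]
    sheet_rows = []
    lib_factors: dict[str, float] = {}
    counts: dict[str, CountMatrix] = {}
    log_lo, log_hi = math.log(config.libsize_range[0]), math.log(config.libsize_range[1])
    for sp in species:
        code = SPECIES_CODES.get(sp, sp.replace(" ", "_").replace(".", ""))
        genes, mus_arr, alphas, og_of_gene = gene_meta[sp]
        og_pos = {og: i for i, og in enumerate(og_ids)}
        sample_ids = []
        mat = []
        for gen in ("F1", "F3"):
            eff_table = effects_f1 if gen == "F1" else effects_f3
            for cond in conditions:
                fold = np.ones(len(genes))
                if cond != "control":
                    eff = eff_table[(sp, cond)].to_numpy()
                    fold = 2.0 ** eff[[og_pos[o] for o in og_of_gene]]
                for r in range(1, config.replicates + 1):
                    sid = f"{code}_{gen}_{cond}_r{r}"
                    sf = math.exp(rng.uniform(log_lo, log_hi))
                    lib_factors[sid] = sf
                    mu = mus_arr * fold * sf
                    mat.append(_draw_counts(rng, mu, alphas))
                    sample_ids.append(sid)
                    sheet_rows.append(
                        {
                            "sample_id": sid,
                            "species": sp,
                            "generation": gen,
                            "parental_condition": cond,
                            "replicate": r,
                        }
                    )
        cm = CountMatrix(genes, sample_ids, np.column_stack(mat), species_tag=sp)
        # guarantee rescue-negative paralogs are observably expressed
        if (rescue_status == "rescue_negative").any():
            for i, g in enumerate(genes):
                if g.endswith("_p2") and rescue_status[og_of_gene[i]] == "rescue_negative":
                    if cm.counts[i].sum() == 0:
                        cm.counts[i, 0] = 1
        counts[sp] = cm

    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    ogs = OrthogroupTable(entries, species)
    truth = SyntheticTruth(
        classes=classes,
        effects_f1=effects_f1,
        effects_f3=effects_f3,
        rescue_status=rescue_status,
        representatives=representatives,
        baselines=baselines,
        dispersions=dispersions,
        library_factors=pd.Series(lib_factors),
    )
    return SyntheticExperiment(counts, sheet, ogs, phenotypes, truth)


def generate_timecourse(
    config: SyntheticConfig, truth: SyntheticTruth, seed: int
) -> EmbryoTimecourse:
    """Reference embryo time course coordinated with the planted effects.

    Trajectories are smooth sinusoids on the regularized-log scale over
    ``n_timepoints`` spanning the configured minute range.  For
    stress-affected C. elegans genes, a ``timing_outside_fraction`` of
    trajectories is built so the stress-condition expression falls
    outside the gene's mean +/- 1 SD embryo band (flat band around the
    control level: the "true not-timing" set); the remainder get a band
    wide enough to cover both conditions.  The planted flags are recorded
    on ``truth.timing_outside``.
    """
    rng = np.random.default_rng(seed)
    sp = "C. elegans"
    if sp not in truth.baselines:
        raise ValidationError("timecourse generation requires C. elegans in the truth")
    genes = list(truth.baselines[sp].index)
    t = np.linspace(*config.time_range_minutes, config.n_timepoints)
    rep = truth.representatives[sp]
    og_of_rep = pd.Series(rep.index.values, index=rep.values)

    # largest-magnitude planted F1 effect per representative gene
    eff_by_gene = pd.Series(0.0, index=genes)
    for (species, stress), eff in truth.effects_f1.items():
        if species != sp:
            continue
        per_gene = eff.reindex(og_of_rep.reindex(genes).dropna()).to_numpy()
        mask = og_of_rep.reindex(genes).notna().to_numpy()
        current = eff_by_gene.to_numpy()
        vals = np.zeros(len(genes))
        vals[mask] = per_gene
        take = np.abs(vals) > np.abs(current)
        eff_by_gene = pd.Series(np.where(take, vals, current), index=genes)

    outside_flags: dict[str, bool] = {}
    rows = np.empty((len(genes), len(t)))
    span = config.time_range_minutes[1] - config.time_range_minutes[0]
    for i, g in enumerate(genes):
        base = truth.baselines[sp][g]
        c = math.log2(base + 1.0)
        period = rng.uniform(0.9 * span, 2.1 * span)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        wave = np.sin(2.0 * math.pi * t / period + phase)
        # standardize over the grid so mean +/- SD is exactly the intended band
        wave = (wave - wave.mean()) / wave.std(ddof=1)
        effect = eff_by_gene[g]
        if effect != 0.0:
            s = math.log2(base * 2.0 ** effect + 1.0)
            d = abs(s - c)
            outside = bool(rng.random() < config.timing_outside_fraction)
            outside_flags[g] = outside
            if outside:
                rows[i] = c + 0.2 * wave  # narrow band around the control level
            else:
                center = 0.5 * (c + s)
                halfwidth = 0.5 * d + 1.0  # band covers both conditions + margin
                rows[i] = center + halfwidth * wave
        else:
            amp = rng.lognormal(mean=math.log(0.5), sigma=0.5)
            rows[i] = c + amp * wave
    truth.timing_outside = pd.Series(outside_flags)
    expr = pd.DataFrame(rows, index=genes, columns=t)
    return EmbryoTimecourse(expr)


def generate_stage_profile(
    timecourse: EmbryoTimecourse,
    minutes: float = 390.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.Series:
    """A whole-sample expression profile drawn from one developmental time.

    Takes the timecourse column nearest ``minutes`` (the comma stage sits
    around 390 min) and adds independent Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    tp = timecourse.timepoints
    col = timecourse.expression.columns[int(np.argmin(np.abs(tp - minutes)))]
    profile = timecourse.expression[col].copy()
    if noise_sd > 0:
        profile = profile + rng.normal(0.0, noise_sd, size=len(profile))
    profile.name = f"profile_{minutes:g}min"
    return profile


@dataclass
class RecoveryScore:
    """Confusion matrix and derived rates for effect-class recovery."""

    confusion: pd.DataFrame  # rows true class, columns predicted class
    per_class: pd.DataFrame  # sensitivity, specificity, f1 per class
    macro_f1: float


def score_recovery(predicted: pd.Series, truth: SyntheticTruth) -> RecoveryScore:
    """Score predicted per-orthogroup class calls against the planted truth.

    ``predicted`` must be indexed by orthogroup ids known to the truth
    (the harmonized universe may be a subset: rescue-negative orthogroups
    never enter it).  Macro-F1 averages F1 over the classes present in
    the truth restricted to the scored orthogroups.
    """
    unknown = predicted.index.difference(truth.classes.index)
    if len(unknown):
        raise ValidationError(
            f"predicted orthogroups unknown to the truth: {list(unknown[:5])}"
        )
    true = truth.classes.reindex(predicted.index)
    labels = sorted(set(true) | set(predicted))
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    for t_cls, p_cls in zip(true, predicted):
        confusion.loc[t_cls, p_cls] += 1
    records = {}
    f1s = []
    total = confusion.to_numpy().sum()
    for cls in labels:
        tp = confusion.loc[cls, cls]
        fn = confusion.loc[cls].sum() - tp
        fp = confusion[cls].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) else float("nan")
        spec = tn / (tn + fp) if (tn + fp) else float("nan")
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        f1 = (
            2 * prec * sens / (prec + sens)
            if (tp + fn) and (prec + sens) > 0
            else (float("nan") if not (tp + fn) else 0.0)
        )
        records[cls] = {"sensitivity": sens, "specificity": spec, "f1": f1}
        if (tp + fn) > 0:  # class present in truth
            f1s.append(f1)
    per_class = pd.DataFrame(records).T
    macro = float(np.mean(f1s)) if f1s else float("nan")
    return RecoveryScore(confusion, per_class, macro)
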