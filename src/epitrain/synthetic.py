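"""Synthetic multi-omics cohort with a ground-truth ledger.

The generator emulates a three-timepoint (T0, T14, T90) BCG-vaccination
methylation cohort: whole-blood beta values confounded by leukocyte
composition and plate batch, spiked time effects in the four trajectory
shapes, baseline CpGs associated with the trained-immunity (TI) cytokine
response, SNP -> methylation-change -> TI mediation triplets with known
coefficients, sex-specific effects and seasonal covariates.  Every spiked
entity is recorded in a :class:`TruthLedger` so downstream stages can be
tested for parameter recovery without any external data.

Methylation is simulated on the M (base-2 logit) scale as Gaussian signal
plus noise and back-transformed, so the beta<->M transform is exact by
construction.  Cell fractions come from a Dirichlet with a dominant
neutrophil-like component, mirroring the composition of whole blood.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_core
from .exceptions import ConfigurationError
from .preprocess import m_to_beta

CYTOKINES = ("TNFa", "IL1b", "IL6", "IFNg")
CELL_TYPES_6 = ("CD4T", "CD8T", "Bcell", "NK", "Mono", "Neu")
#: whole-blood mean fractions; the neutrophil-like component dominates
CELL_MEANS_6 = (0.15, 0.10, 0.08, 0.05, 0.07, 0.55)
TRAJECTORY_CLASSES = ("down_down", "down_up", "up_down", "up_up")


@dataclass
class TrajectoryEffect:
    """Spiked time effect for one trajectory class (M units vs T0)."""

    n: int
    d14: float
    d90: float


def _default_trajectory_effects() -> dict:
    return {
        "down_down": TrajectoryEffect(5, -0.6, -1.0),
        "down_up": TrajectoryEffect(5, -0.8, 0.8),
        "up_down": TrajectoryEffect(5, 0.8, -0.8),
        "up_up": TrajectoryEffect(5, 0.6, 1.0),
    }


def _default_variance_fractions() -> dict:
    return {"methylation": 0.30, "metabolites": 0.10, "genetics": 0.05,
            "proteins": 0.0}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; ``seed`` makes output byte-identical.

    Sizes default to the analysed discovery cohort (284 subjects, 126 M /
    158 F) with the probe/SNP dimensions scaled down to what the analyses
    need to be exercised end-to-end.
    """

    n_subjects: int = 284
    n_probes: int = 2000
    n_snps: int = 200
    n_cell_types: int = 6
    n_batches: int = 8
    female_fraction: float = 158 / 284

    # spiked effect blocks
    trajectory_effects: dict = field(default_factory=_default_trajectory_effects)
    n_ti_probes: int = 10
    ti_variance_fractions: dict = field(default_factory=_default_variance_fractions)
    n_mediation_triplets: int = 5
    mediation_a: float = 0.5
    mediation_b: float = 0.4
    mediation_c: float = 0.3
    mediation_noise_m: float = 0.5
    mediation_noise_y: float = 0.5
    n_sex_probes: int = 3
    sex_effect: float = 1.0
    n_seasonal_probes: int = 5
    seasonal_amplitude: float = 0.5

    # noise scales (M units unless stated)
    sd_subject: float = 0.5
    sd_noise: float = 1.0
    batch_sd: float = 0.3
    cell_effect_sd: float = 1.5
    marker_effect: float = 4.0
    markers_per_cell_type: int = 10
    dirichlet_concentration: float = 50.0

    # cytokine / layer tables
    n_cyto_batches: int = 4
    cyto_batch_sd: float = 0.2
    n_proteins: int = 73
    n_metabolites: int = 100
    n_hormones: int = 5

    maf_min: float = 0.05
    maf_max: float = 0.5
    n_chromosomes: int = 5
    chrom_length: int = 50_000_000

    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.trajectory_effects, dict):
            self.trajectory_effects = {
                k: v if isinstance(v, TrajectoryEffect) else TrajectoryEffect(*v)
                for k, v in self.trajectory_effects.items()
            }

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in ("n_subjects", "n_probes", "n_snps", "n_cell_types",
                     "n_batches", "n_cyto_batches"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("n_ti_probes", "n_mediation_triplets", "n_sex_probes",
                     "n_seasonal_probes", "n_proteins", "n_metabolites",
                     "n_hormones"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must be in [0, 1]")
        if not 0.0 < self.maf_min <= self.maf_max <= 0.5:
            raise ConfigurationError("maf_min/maf_max must satisfy 0 < min <= max <= 0.5")
        unknown = set(self.trajectory_effects) - set(TRAJECTORY_CLASSES)
        if unknown:
            raise ConfigurationError(
                f"trajectory_effects has unknown classes {sorted(unknown)}")
        if self.n_spiked_probes > self.n_probes:
            raise ConfigurationError(
                "effect-block probe counts exceed n_probes "
                f"({self.n_spiked_probes} > {self.n_probes})")
        frac_sum = sum(self.ti_variance_fractions.values())
        if frac_sum >= 1.0 or any(v < 0 for v in self.ti_variance_fractions.values()):
            raise ConfigurationError(
                "ti_variance_fractions must be nonnegative and sum to < 1")
        if self.n_mediation_triplets > self.n_snps:
            raise ConfigurationError("n_mediation_triplets exceeds n_snps")

    @property
    def n_spiked_probes(self) -> int:
        n_traj = sum(t.n for t in self.trajectory_effects.values())
        markers = self.markers_per_cell_type * self.n_cell_types
        return (n_traj + self.n_ti_probes + self.n_mediation_triplets
                + self.n_sex_probes + self.n_seasonal_probes + markers)

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A configuration with every spiked effect block empty."""
        base = dict(
            trajectory_effects={},
            n_ti_probes=0,
            ti_variance_fractions={},
            n_mediation_triplets=0,
            n_sex_probes=0,
            n_seasonal_probes=0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TruthLedger:
    """Ground truth of every spiked effect in a generated cohort."""

    trajectory: dict = field(default_factory=dict)      # probe -> class/d14/d90
    ti_probes: dict = field(default_factory=dict)       # probe -> {cytokine: coef}
    mediation: list = field(default_factory=list)       # triplet dicts
    variance_fractions: dict = field(default_factory=dict)
    sex_probes: dict = field(default_factory=dict)      # probe -> {sex, d14, d90}
    seasonal_probes: dict = field(default_factory=dict)  # probe -> amplitude
    cell_reference: pd.DataFrame | None = None          # marker probes x cell types

    def to_json(self, path) -> None:
        payload = {
            "trajectory": self.trajectory,
            "ti_probes": self.ti_probes,
            "mediation": self.mediation,
            "variance_fractions": self.variance_fractions,
            "sex_probes": self.sex_probes,
            "seasonal_probes": self.seasonal_probes,
            "cell_reference": (
                None if self.cell_reference is None
                else {
                    "index": list(self.cell_reference.index),
                    "columns": list(self.cell_reference.columns),
                    "values": self.cell_reference.to_numpy().tolist(),
                }
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        payload = json.loads(Path(path).read_text())
        ref = payload.pop("cell_reference", None)
        ledger = cls(**payload)
        if ref is not None:
            ledger.cell_reference = pd.DataFrame(
                ref["values"],
                index=pd.Index(ref["index"], name="probe_id"),
                columns=ref["columns"])
        return ledger


@dataclass
class Cohort:
    """Everything :func:`generate_cohort` produces."""

    betas: pd.DataFrame               # probes x samples, beta scale
    samples: pd.DataFrame             # sample sheet
    cell_fractions: pd.DataFrame      # samples x cell types (truth)
    dosages: pd.DataFrame             # snp_id x (chrom, pos, subjects)
    annotation: pd.DataFrame          # probe annotation
    cytokines: pd.DataFrame           # long table with conc_T0 / conc_T90
    layers: dict                      # name -> subjects x features
    ledger: TruthLedger


def _mediation_acme(a: float, b: float, c: float) -> tuple[float, float]:
    acme = a * b
    total = acme + c
    prop = acme / total if total != 0 else np.nan
    return acme, prop


def simulate_mediation_dataset(
    a: float, b: float, c_prime: float, n: int, *,
    noise_m: float = 0.5, noise_y: float = 0.5, maf: float = 0.3,
    rng=None, seed: int | None = None, reverse: bool = False,
):
    """Simulate one SNP -> mediator -> outcome triplet.

    ``m = a*g + eps1``, ``y = b*m + c'*g + eps2`` with g ~ Binomial(2, maf).
    With ``reverse=True`` the mediator/outcome roles are generated the other
    way around (g -> y -> m), for testing direction triage.
    Returns (g, m, y).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    g = rng.binomial(2, maf, size=n).astype(float)
    if reverse:
        y = a * g + rng.normal(0, noise_m, n)
        m = b * y + c_prime * g + rng.normal(0, noise_y, n)
    else:
        m = a * g + rng.normal(0, noise_m, n)
        y = b * m + c_prime * g + rng.normal(0, noise_y, n)
    return g, m, y


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _draw_base_m(rng, n_probes: int) -> np.ndarray:
    """Trimodal baseline M values: hypo / intermediate / hyper probes."""
    cls = rng.choice(3, size=n_probes, p=(0.35, 0.30, 0.35))
    means = np.array([-2.5, 0.0, 2.5])[cls]
    return means + rng.normal(0.0, 0.8, n_probes)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sub, n_probes, n_snps = config.n_subjects, config.n_probes, config.n_snps
    subjects = [f"S{i:04d}" for i in range(n_sub)]
    tps = list(io_core.TIMEPOINTS)
    samples = [f"{s}_{tp}" for s in subjects for tp in tps]
    n_samples = len(samples)

    # ----- sample sheet ----------------------------------------------------
    n_f = int(round(config.female_fraction * n_sub))
    sex = np.array(["F"] * n_f + ["M"] * (n_sub - n_f))
    rng.shuffle(sex)
    age = np.clip(18 + rng.gamma(2.0, 4.0, n_sub), 18, 71).round(1)
    bmi = rng.normal(22.5, 2.5, n_sub).round(2)
    smoking = rng.random(n_sub) < 0.2
    t0_date = pd.Timestamp("2017-04-01") + pd.to_timedelta(
        rng.integers(0, 365, n_sub), unit="D")
    offsets = {"T0": 0, "T14": 14, "T90": 90}
    plate = rng.integers(0, config.n_batches, n_samples)
    sheet = pd.DataFrame({
        "sample_id": samples,
        "subject_id": np.repeat(subjects, len(tps)),
        "timepoint": np.tile(tps, n_sub),
        "age": np.repeat(age, len(tps)),
        "sex": np.repeat(sex, len(tps)),
        "plate": [f"P{p + 1}" for p in plate],
        "collection_date": [
            t0_date[i] + pd.Timedelta(days=offsets[tp])
            for i in range(n_sub) for tp in tps
        ],
        "bmi": np.repeat(bmi, len(tps)),
        "smoking": np.repeat(smoking, len(tps)),
    })

    # ----- probe layout ----------------------------------------------------
    probes = [f"cg{i:08d}" for i in range(n_probes)]
    chrom = rng.integers(1, config.n_chromosomes + 1, n_probes).astype(str)
    pos = rng.integers(1, config.chrom_length, n_probes)
    annotation = pd.DataFrame({
        "probe_id": probes, "chromosome": chrom, "position": pos,
        "nearest_gene": [f"GENE{i}" if i % 3 else "" for i in range(n_probes)],
    }).set_index("probe_id", drop=False)

    # assign disjoint spiked probe blocks
    ledger = TruthLedger(variance_fractions=dict(config.ti_variance_fractions))
    perm = rng.permutation(n_probes)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        idx = perm[cursor:cursor + k]
        cursor += k
        return [probes[i] for i in idx]

    traj_probes: dict[str, TrajectoryEffect] = {}
    for cls_name in TRAJECTORY_CLASSES:
        eff = config.trajectory_effects.get(cls_name)
        if eff is None or eff.n == 0:
            continue
        for p in take(eff.n):
            traj_probes[p] = eff
            ledger.trajectory[p] = {"class": cls_name, "d14": eff.d14,
                                    "d90": eff.d90}
    ti_probes = take(config.n_ti_probes)
    med_probes = take(config.n_mediation_triplets)
    sex_probes = take(config.n_sex_probes)
    seasonal_probes = take(config.n_seasonal_probes)
    marker_probes = take(config.markers_per_cell_type * config.n_cell_types)

    # ----- genotypes -------------------------------------------------------
    snp_ids = [f"rs{i:06d}" for i in range(n_snps)]
    mafs = rng.uniform(config.maf_min, config.maf_max, n_snps)
    dosage_vals = rng.binomial(2, mafs[:, None], (n_snps, n_sub)).astype(float)
    snp_chrom = rng.integers(1, config.n_chromosomes + 1, n_snps).astype(str)
    snp_pos = rng.integers(1, config.chrom_length, n_snps)
    # mediation SNPs sit in cis of their probe (within the 250 kb window)
    med_snps = [snp_ids[j] for j in range(config.n_mediation_triplets)]
    for j, probe in enumerate(med_probes):
        snp_chrom[j] = annotation.loc[probe, "chromosome"]
        snp_pos[j] = max(1, int(annotation.loc[probe, "position"])
                         + int(rng.integers(-200_000, 200_000)))
    dosages = pd.DataFrame(dosage_vals, index=pd.Index(snp_ids, name="snp_id"),
                           columns=subjects)
    dosages.insert(0, "chrom", snp_chrom)
    dosages.insert(1, "pos", snp_pos)

    # ----- cell composition ------------------------------------------------
    cell_types = list(CELL_TYPES_6[:config.n_cell_types])
    if config.n_cell_types > len(CELL_TYPES_6):
        cell_types += [f"Cell{i}" for i in range(len(CELL_TYPES_6),
                                                 config.n_cell_types)]
    means = np.asarray(CELL_MEANS_6[:config.n_cell_types], dtype=float)
    if len(means) < config.n_cell_types:
        means = np.append(means, np.full(config.n_cell_types - len(means), 0.05))
    means = means / means.sum()
    alpha = config.dirichlet_concentration * means
    fracs = rng.dirichlet(alpha, n_samples)
    cell_fractions = pd.DataFrame(fracs, index=samples, columns=cell_types)

    # cell-type deviations on the M scale: strong on marker probes, diffuse
    # on a random 30% of the remaining probes
    probe_pos = {p: i for i, p in enumerate(probes)}
    cell_dev = np.zeros((n_probes, config.n_cell_types))
    for k in range(config.n_cell_types):
        block = marker_probes[k * config.markers_per_cell_type:
                              (k + 1) * config.markers_per_cell_type]
        for p in block:
            cell_dev[probe_pos[p], k] = config.marker_effect
    diffuse = rng.random(n_probes) < 0.3
    protected = set(ti_probes) | set(med_probes)
    for p in protected:
        diffuse[probe_pos[p]] = False
    cell_dev[diffuse] += rng.normal(0.0, config.cell_effect_sd,
                                    (int(diffuse.sum()), config.n_cell_types))

    # ----- assemble M values ----------------------------------------------
    m0 = _draw_base_m(rng, n_probes)
    m = np.tile(m0[:, None], (1, n_samples))
    m += cell_dev @ fracs.T
    plate_shift = rng.normal(0.0, config.batch_sd, (n_probes, config.n_batches))
    m += plate_shift[:, plate]
    subj_int = rng.normal(0.0, config.sd_subject, (n_probes, n_sub))
    subj_of_sample = np.repeat(np.arange(n_sub), len(tps))
    m += subj_int[:, subj_of_sample]

    tp_of_sample = np.tile(np.arange(len(tps)), n_sub)  # 0=T0, 1=T14, 2=T90
    is_t14 = tp_of_sample == 1
    is_t90 = tp_of_sample == 2
    for p, eff in traj_probes.items():
        i = probe_pos[p]
        m[i, is_t14] += eff.d14
        m[i, is_t90] += eff.d90
    female_sample = np.repeat(sex == "F", len(tps))
    for p in sex_probes:
        i = probe_pos[p]
        m[i, is_t90 & female_sample] += config.sex_effect
        ledger.sex_probes[p] = {"sex": "F", "d14": 0.0,
                                "d90": config.sex_effect}
    doy = sheet["collection_date"].dt.dayofyear.to_numpy()
    season = np.sin(2 * np.pi * doy / 365.25)
    for p in seasonal_probes:
        i = probe_pos[p]
        m[i] += config.seasonal_amplitude * season
        ledger.seasonal_probes[p] = config.seasonal_amplitude

    # stable subject-level deviations for the TI-associated baseline probes
    ti_latent = rng.normal(0.0, 1.0, (len(ti_probes), n_sub))
    for j, p in enumerate(ti_probes):
        m[probe_pos[p]] += ti_latent[j, subj_of_sample]

    # mediation triplets: T90 - T0 change of the probe is a*g + eps1
    med_changes = np.zeros((config.n_mediation_triplets, n_sub))
    for j, (snp, probe) in enumerate(zip(med_snps, med_probes)):
        g = dosage_vals[j] - dosage_vals[j].mean()
        eps1 = rng.normal(0.0, config.mediation_noise_m, n_sub)
        change = config.mediation_a * g + eps1
        med_changes[j] = change
        m[probe_pos[probe], is_t90] += change
        acme, prop = _mediation_acme(config.mediation_a, config.mediation_b,
                                     config.mediation_c)
        ledger.mediation.append({
            "snp": snp, "probe": probe, "cytokine": "IFNg",
            "a": config.mediation_a, "b": config.mediation_b,
            "c_prime": config.mediation_c, "acme": acme,
            "prop_mediated": prop,
        })

    m += rng.normal(0.0, config.sd_noise, (n_probes, n_samples))
    np.clip(m, -25.0, 25.0, out=m)
    betas = pd.DataFrame(m_to_beta(m), index=pd.Index(probes, name="probe_id"),
                         columns=samples)

    # reference panel: noise-free marker-probe profiles on the beta scale
    ref_rows = [probe_pos[p] for p in marker_probes]
    ref_m = m0[ref_rows, None] + cell_dev[ref_rows]
    ledger.cell_reference = pd.DataFrame(
        m_to_beta(ref_m), index=pd.Index(marker_probes, name="probe_id"),
        columns=cell_types)

    # ----- omics layers ----------------------------------------------------
    layers = {
        "proteins": pd.DataFrame(
            rng.normal(size=(n_sub, config.n_proteins)), index=subjects,
            columns=[f"PROT{i:03d}" for i in range(config.n_proteins)]),
        "metabolites": pd.DataFrame(
            rng.normal(size=(n_sub, config.n_metabolites)), index=subjects,
            columns=[f"MET{i:03d}" for i in range(config.n_metabolites)]),
        "hormones": pd.DataFrame(
            rng.normal(size=(n_sub, config.n_hormones)), index=subjects,
            columns=["ADNC", "CORC", "DESC", "HPGC", "TESC"][:config.n_hormones]),
    }
    wbc = rng.normal(6.0, 1.0, n_sub)
    t0_fracs = cell_fractions.loc[[f"{s}_T0" for s in subjects]].to_numpy()
    layers["cell_counts"] = pd.DataFrame(
        t0_fracs * wbc[:, None] + rng.normal(0, 0.05, t0_fracs.shape),
        index=subjects, columns=[f"{c}_count" for c in cell_types])

    # ----- trained-immunity outcome ---------------------------------------
    fr = config.ti_variance_fractions
    signal = {cyt: np.zeros(n_sub) for cyt in CYTOKINES}
    explained = 0.0
    if ti_probes and fr.get("methylation", 0) > 0:
        t0_cols = [f"{s}_T0" for s in subjects]
        obs = np.vstack([
            _standardize(betas.loc[p, t0_cols].to_numpy(dtype=float))
            for p in ti_probes])
        z_meth = _standardize(obs.mean(axis=0))
        w = np.sqrt(fr["methylation"])
        signal["IFNg"] += w * z_meth
        explained += fr["methylation"]
        for p in ti_probes:
            # marginal slope of ti_norm per SD of probe beta at baseline
            ledger.ti_probes[p] = {"IFNg": w / np.sqrt(len(ti_probes))}
    if fr.get("metabolites", 0) > 0 and config.n_metabolites >= 5:
        z = _standardize(layers["metabolites"].iloc[:, :5].mean(axis=1).to_numpy())
        signal["IFNg"] += np.sqrt(fr["metabolites"]) * z
        explained += fr["metabolites"]
    if fr.get("genetics", 0) > 0:
        n_prs = min(10, n_snps - config.n_mediation_triplets)
        prs_idx = np.arange(config.n_mediation_triplets,
                            config.n_mediation_triplets + n_prs)
        weights = rng.normal(size=n_prs)
        z = _standardize(weights @ dosage_vals[prs_idx])
        signal["IFNg"] += np.sqrt(fr["genetics"]) * z
        explained += fr["genetics"]
    if fr.get("proteins", 0) > 0:
        z = _standardize(layers["proteins"].iloc[:, :5].mean(axis=1).to_numpy())
        signal["IFNg"] += np.sqrt(fr["proteins"]) * z
        explained += fr["proteins"]
    # mediation paths feed the same outcome; the rest of the TI signal (other
    # layers + residual) is the outcome-model error term, so no separate
    # per-triplet noise is added here
    med_contrib = np.zeros(n_sub)
    for j in range(config.n_mediation_triplets):
        g = dosage_vals[j] - dosage_vals[j].mean()
        med_contrib += config.mediation_b * med_changes[j] + config.mediation_c * g
    signal["IFNg"] += med_contrib
    resid_sd = np.sqrt(max(1.0 - explained - float(med_contrib.var()), 0.01))
    for cyt in CYTOKINES:
        if cyt == "IFNg":
            signal[cyt] += resid_sd * rng.normal(size=n_sub)
        else:
            signal[cyt] += rng.normal(size=n_sub)

    cyto_batch = rng.integers(0, config.n_cyto_batches, n_sub)
    batch_shift = rng.normal(0.0, config.cyto_batch_sd, config.n_cyto_batches)
    rows = []
    for cyt in CYTOKINES:
        base = rng.normal(2.0, 0.5, n_sub)
        log_fc = signal[cyt] + batch_shift[cyto_batch]
        rows.append(pd.DataFrame({
            "subject_id": subjects, "cytokine": cyt,
            "conc_T0": 10.0 ** base, "conc_T90": 10.0 ** (base + log_fc),
            "batch": [f"B{b + 1}" for b in cyto_batch],
        }))
    cytokines = pd.concat(rows, ignore_index=True)

    return Cohort(betas=betas, samples=sheet, cell_fractions=cell_fractions,
                  dosages=dosages, annotation=annotation, cytokines=cytokines,
                  layers=layers, ledger=ledger)


def generate_replication(
    config: CohortConfig,
    ledger: TruthLedger,
    *,
    n_subjects: int = 17,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a two-timepoint (T0, T90) replication cohort.

    Re-uses the spiked effect directions recorded in ``ledger`` (trajectory
    d90 effects and the baseline-methylation -> TI coefficients) at a smaller
    sample size with independent noise; defaults to the 17-subject scale of a
    booster-trial replication arm.

    Returns (betas, sample_sheet, cytokines).
    """
    if ledger is None:
        raise ConfigurationError("generate_replication requires a TruthLedger")
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    subjects = [f"R{i:04d}" for i in range(n_subjects)]
    tps = ["T0", "T90"]
    samples = [f"{s}_{tp}" for s in subjects for tp in tps]
    n_samples = len(samples)
    probes = [f"cg{i:08d}" for i in range(config.n_probes)]
    probe_pos = {p: i for i, p in enumerate(probes)}

    n_f = int(round(config.female_fraction * n_subjects))
    sex = np.array(["F"] * n_f + ["M"] * (n_subjects - n_f))
    rng.shuffle(sex)
    t0_date = pd.Timestamp("2019-06-01") + pd.to_timedelta(
        rng.integers(0, 365, n_subjects), unit="D")
    sheet = pd.DataFrame({
        "sample_id": samples,
        "subject_id": np.repeat(subjects, 2),
        "timepoint": np.tile(tps, n_subjects),
        "age": np.repeat(np.clip(18 + rng.gamma(2.0, 4.0, n_subjects), 18, 71).round(1), 2),
        "sex": np.repeat(sex, 2),
        "plate": [f"P{p + 1}" for p in rng.integers(0, 2, n_samples)],
        "collection_date": [t0_date[i] + pd.Timedelta(days=d)
                            for i in range(n_subjects) for d in (0, 90)],
        "bmi": np.repeat(rng.normal(22.5, 2.5, n_subjects).round(2), 2),
        "smoking": np.repeat(rng.random(n_subjects) < 0.2, 2),
    })

    m0 = _draw_base_m(rng, config.n_probes)
    m = np.tile(m0[:, None], (1, n_samples))
    subj_of_sample = np.repeat(np.arange(n_subjects), 2)
    m += rng.normal(0.0, config.sd_subject,
                    (config.n_probes, n_subjects))[:, subj_of_sample]
    is_t90 = np.tile([False, True], n_subjects)
    for p, info in ledger.trajectory.items():
        if p in probe_pos:
            m[probe_pos[p], is_t90] += info["d90"]

    ti_latent = {}
    for p in ledger.ti_probes:
        if p in probe_pos:
            q = rng.normal(0.0, 1.0, n_subjects)
            m[probe_pos[p]] += q[subj_of_sample]
            ti_latent[p] = q
    m += rng.normal(0.0, config.sd_noise, (config.n_probes, n_samples))
    np.clip(m, -25.0, 25.0, out=m)
    betas = pd.DataFrame(m_to_beta(m), index=pd.Index(probes, name="probe_id"),
                         columns=samples)

    signal = {cyt: np.zeros(n_subjects) for cyt in CYTOKINES}
    if ti_latent:
        t0_cols = [f"{s}_T0" for s in subjects]
        obs = np.vstack([
            _standardize(betas.loc[p, t0_cols].to_numpy(dtype=float))
            for p in ti_latent])
        w = np.sqrt(ledger.variance_fractions.get("methylation", 0.0))
        signal["IFNg"] += w * _standardize(obs.mean(axis=0))
    rows = []
    for cyt in CYTOKINES:
        base = rng.normal(2.0, 0.5, n_subjects)
        log_fc = signal[cyt] + rng.normal(0.0, 1.0, n_subjects) * np.sqrt(
            max(1.0 - ledger.variance_fractions.get("methylation", 0.0), 0.0)
            if cyt == "IFNg" else 1.0)
        rows.append(pd.DataFrame({
            "subject_id": subjects, "cytokine": cyt,
            "conc_T0": 10.0 ** base, "conc_T90": 10.0 ** (base + log_fc),
            "batch": "B1",
        }))
    return betas, sheet, pd.concat(rows, ignore_index=True)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write every cohort table in the formats the IO layer reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_core.write_matrix(cohort.betas, out / "betas.tsv")
    io_core.write_sample_sheet(cohort.samples, out / "samples.csv")
    io_core.write_matrix(cohort.cell_fractions.T, out / "cell_fractions.tsv")
    io_core.write_dosages(cohort.dosages, out / "dosages.tsv")
    io_core.write_probe_annotation(cohort.annotation, out / "annotation.tsv")
    cohort.cytokines.to_csv(out / "cytokines.csv", index=False)
    for name, table in cohort.layers.items():
        io_core.write_matrix(table.T, out / f"layer_{name}.tsv")
    io_core.write_matrix(cohort.ledger.cell_reference, out / "cell_reference.tsv")
    cohort.ledger.to_json(out / "truth_ledger.json")
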