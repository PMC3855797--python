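"""Synthetic twin-cohort generator with known variance structure.

Generates the four tables the downstream stages consume — twin pair table,
covariates, trait matrix, glycan peak matrix and methylation matrix — from a
single :class:`SimulationConfig`, so that every estimate produced later can be
checked against planted ground truth.

The trait-generating model follows the classical twin (ACE) decomposition: on
the standardized scale each trait is

    y = sqrt(a2)*A + sqrt(c2)*C + sqrt(e2)*E  (+ covariate and probe effects)

where A is shared exactly between monozygotic (MZ) co-twins and correlated 0.5
between dizygotic (DZ) co-twins (implemented by splitting A into a shared and a
segregating half), C is shared within every pair, and E is individual noise.
The implied cross-twin covariance is a2 + c2 for MZ pairs and 0.5*a2 + c2 for
DZ pairs, with unit marginal variance before covariate effects are added.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraitSpec",
    "CovariateModel",
    "PeakModel",
    "PlantedEffect",
    "MethylModel",
    "SimulationConfig",
    "SyntheticCohort",
    "stage_rng",
    "simulate_twin_trait",
    "simulate_covariates",
    "simulate_peak_profiles",
    "simulate_methylation",
    "simulate_cohort",
]

N_PEAKS = 24

#: Default mean percentages for the 24 UPLC glycan peaks (% of total integrated
#: area).  Anchored to the MZ column means of the study cohort where a peak is
#: reported; GP3 and GP20 (not reported there) are given small filler means and
#: the vector is rescaled to sum to exactly 100.
DEFAULT_PEAK_MEANS = {
    "GP1": 0.10, "GP2": 0.48, "GP3": 0.05, "GP4": 19.41, "GP5": 0.32,
    "GP6": 5.33, "GP7": 0.54, "GP8": 18.97, "GP9": 9.98, "GP10": 6.00,
    "GP11": 0.84, "GP12": 0.67, "GP13": 0.50, "GP14": 14.33, "GP15": 1.86,
    "GP16": 3.30, "GP17": 0.94, "GP18": 9.54, "GP19": 1.86, "GP20": 0.20,
    "GP21": 1.32, "GP22": 0.15, "GP23": 1.65, "GP24": 1.93,
}


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class TraitSpec:
    """Standardized variance shares for one simulated trait (a2+c2+e2=1)."""

    name: str
    a2: float
    c2: float
    e2: float

    def validate(self) -> None:
        comps = (self.a2, self.c2, self.e2)
        if any(c < 0 for c in comps):
            raise InvalidConfigError(
                f"trait {self.name!r}: negative variance component {comps}"
            )
        if abs(sum(comps) - 1.0) > 1e-8:
            raise InvalidConfigError(
                f"trait {self.name!r}: a2+c2+e2 = {sum(comps)} != 1"
            )


@dataclass(frozen=True)
class CovariateModel:
    """Covariate-generating model (all-female twin cohort).

    Ages are drawn per pair (co-twins share age) from a common normal law for
    both zygosity groups; BMI is individual.  ``age_beta`` and ``batch_sd``
    set the per-trait covariate effects: a linear slope on centred age, and a
    batch offset drawn once per batch from N(0, batch_sd**2).
    """

    age_mean: float = 58.4
    age_sd: float = 9.5
    bmi_mean: float = 26.6
    bmi_sd: float = 4.8
    n_batches: int = 4
    chip_size: int = 12
    age_beta: float = 0.01
    batch_sd: float = 0.1


@dataclass(frozen=True)
class PeakModel:
    """Dirichlet composition model for the 24-peak profile.

    ``means`` are expected percentages summing to 100; ``dispersion`` is the
    inverse Dirichlet concentration, so larger values give noisier profiles
    (per-peak variance = p*(1-p)/(1/dispersion + 1) on the proportion scale).
    The default dispersion (1/36) matches the coefficient of variation of the
    major peaks in the study cohort (e.g. GP4 mean 19.4%, SD ~6.5%).
    """

    means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_MEANS)
    )
    dispersion: float = 1.0 / 36.0

    def mean_vector(self) -> np.ndarray:
        vals = np.array([self.means[f"GP{i}"] for i in range(1, N_PEAKS + 1)])
        return vals

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise InvalidConfigError("peak dispersion must be > 0")
        missing = [f"GP{i}" for i in range(1, N_PEAKS + 1) if f"GP{i}" not in self.means]
        if missing:
            raise InvalidConfigError(f"peak means missing for {missing}")
        total = float(self.mean_vector().sum())
        if abs(total - 100.0) > 0.5:
            raise InvalidConfigError(f"peak means sum to {total}, expected 100")


@dataclass(frozen=True)
class PlantedEffect:
    """A known (probe, trait, beta) association planted into the cohort."""

    probe: str
    trait: str
    beta: float


@dataclass(frozen=True)
class MethylModel:
    """Methylation-generating model on the standardized (z) scale.

    Null probes are family-shared intercept plus individual noise, then
    column-standardized.  ``family_var`` is the within-pair shared fraction of
    the probe variance; it is a free parameter of the generator, not a
    published quantity.
    """

    n_probes: int = 200
    family_var: float = 0.2
    planted: tuple[PlantedEffect, ...] = ()

    def validate(self) -> None:
        if not 0 <= self.family_var < 1:
            raise InvalidConfigError("family_var must be in [0, 1)")
        if self.n_probes < len(self.planted):
            raise InvalidConfigError("n_probes smaller than planted-effect count")


def _default_trait_specs() -> tuple[TraitSpec, ...]:
    # spans the range of fitted variance shares seen across the 76 study
    # traits: strong AE, moderate ACE, CE-only and pure-noise traits
    return (
        TraitSpec("trait_ae_high", 0.80, 0.00, 0.20),
        TraitSpec("trait_ae_mid", 0.70, 0.00, 0.30),
        TraitSpec("trait_ace_a", 0.45, 0.29, 0.26),
        TraitSpec("trait_ace_b", 0.36, 0.37, 0.27),
        TraitSpec("trait_ce_high", 0.00, 0.66, 0.34),
        TraitSpec("trait_ce_low", 0.00, 0.28, 0.72),
        TraitSpec("trait_e_only", 0.00, 0.00, 1.00),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full ground-truth description of a synthetic twin cohort.

    Defaults reproduce the study conditions: 220 MZ + 310 DZ female pairs,
    trait variance structures spanning the fitted range, peak composition
    anchored to the reported means, and standardized methylation probes.
    """

    n_mz: int = 220
    n_dz: int = 310
    trait_specs: tuple[TraitSpec, ...] = field(default_factory=_default_trait_specs)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    peak_model: PeakModel = field(default_factory=PeakModel)
    methyl_model: MethylModel = field(default_factory=MethylModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_mz < 1 or self.n_dz < 1:
            raise InvalidConfigError("need at least one pair per zygosity group")
        names = [t.name for t in self.trait_specs]
        if len(set(names)) != len(names):
            raise InvalidConfigError("duplicate trait names in trait_specs")
        for spec in self.trait_specs:
            spec.validate()
        self.peak_model.validate()
        self.methyl_model.validate()
        for eff in self.methyl_model.planted:
            if eff.trait not in names:
                raise InvalidConfigError(
                    f"planted effect references unknown trait {eff.trait!r}"
                )

    # -- round-trippable serialization -------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["trait_specs"] = tuple(TraitSpec(**t) for t in d.get("trait_specs", []))
        if "covariate_model" in d:
            d["covariate_model"] = CovariateModel(**d["covariate_model"])
        if "peak_model" in d:
            d["peak_model"] = PeakModel(**d["peak_model"])
        if "methyl_model" in d:
            m = dict(d["methyl_model"])
            m["planted"] = tuple(PlantedEffect(**p) for p in m.get("planted", []))
            d["methyl_model"] = MethylModel(**m)
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream derived from the master seed.

    The child seed is a SHA-256 digest of ``"{seed}:{stage}"`` truncated to
    31 bits, so stage streams are independent of each other and stable across
    runs and platforms.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    child = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(child)


def simulate_twin_trait(
    n_mz: int,
    n_dz: int,
    a2: float,
    c2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw standardized paired trait values for MZ and DZ twin pairs.

    Each pair is bivariate normal with zero mean, unit variances, and
    cross-twin covariance ``a2 + c2`` (MZ) or ``0.5*a2 + c2`` (DZ).

    Returns
    -------
    (mz, dz) : arrays of shape (n_mz, 2) and (n_dz, 2)
    """
    if a2 < 0 or c2 < 0 or a2 + c2 > 1 + 1e-12:
        raise InvalidConfigError(f"invalid variance components a2={a2}, c2={c2}")
    e2 = max(0.0, 1.0 - a2 - c2)

    sa, sc, se = np.sqrt(a2), np.sqrt(c2), np.sqrt(e2)

    a_mz = rng.standard_normal(n_mz)  # additive factor, fully shared
    c_mz = rng.standard_normal(n_mz)
    e_mz = rng.standard_normal((n_mz, 2))
    mz = sa * a_mz[:, None] + sc * c_mz[:, None] + se * e_mz

    # DZ additive factor: shared half + segregating half per twin
    a_shared = rng.standard_normal(n_dz)
    a_seg = rng.standard_normal((n_dz, 2))
    a_dz = np.sqrt(0.5) * a_shared[:, None] + np.sqrt(0.5) * a_seg
    c_dz = rng.standard_normal(n_dz)
    e_dz = rng.standard_normal((n_dz, 2))
    dz = sa * a_dz + sc * c_dz[:, None] + se * e_dz
    return mz, dz


def _make_pair_table(n_mz: int, n_dz: int) -> pd.DataFrame:
    rows = []
    k = 0
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        for _ in range(n):
            k += 1
            pid = f"fam{k:04d}"
            rows.append(
                {
                    "pair_id": pid,
                    "zygosity": zyg,
                    "sample_1": f"{pid}_1",
                    "sample_2": f"{pid}_2",
                }
            )
    return pd.DataFrame(rows)


def simulate_covariates(
    pair_table: pd.DataFrame,
    model: CovariateModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-sample covariate table: age, sex, BMI, batch, chip, chip position.

    Co-twins share age (and family id); sex is constant female; batches are
    assigned uniformly at random and chips in consecutive blocks of
    ``chip_size`` samples with the within-chip position recorded.
    """
    if pair_table.empty:
        raise InvalidConfigError("pair table is empty")
    ages = model.age_mean + model.age_sd * rng.standard_normal(len(pair_table))
    rows = []
    for (_, pair), age in zip(pair_table.iterrows(), ages):
        for member in ("sample_1", "sample_2"):
            rows.append(
                {
                    "sample_id": pair[member],
                    "pair_id": pair["pair_id"],
                    "zygosity": pair["zygosity"],
                    "age": age,
                    "sex": "F",
                    "bmi": model.bmi_mean + model.bmi_sd * rng.standard_normal(),
                    "batch": int(rng.integers(1, model.n_batches + 1)),
                }
            )
    cov = pd.DataFrame(rows)
    idx = np.arange(len(cov))
    cov["chip"] = idx // model.chip_size + 1
    cov["chip_position"] = idx % model.chip_size + 1
    return cov


def simulate_peak_profiles(
    n_samples: int,
    model: PeakModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw 24-peak compositional profiles (rows sum to exactly 100).

    Rows are Dirichlet with concentration ``mean_i/100 / dispersion``, so the
    expected value of every peak equals its configured mean.
    """
    model.validate()
    means = model.mean_vector()
    means = means / means.sum()  # exact simplex after the +-0.5 validation
    alpha = means / model.dispersion
    comps = rng.dirichlet(alpha, size=n_samples) * 100.0
    return pd.DataFrame(comps, columns=[f"GP{i}" for i in range(1, N_PEAKS + 1)])


def simulate_methylation(
    pair_table: pd.DataFrame,
    trait_matrix: pd.DataFrame,
    model: MethylModel,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardized methylation matrix plus planted trait effects.

    Each probe is a family-shared intercept (variance ``family_var``) plus
    individual noise, column-standardized to mean 0 and unit sample variance.
    For every planted (probe, trait, beta) the returned trait matrix includes
    ``beta * probe`` added to that trait, so a downstream regression of the
    trait on the probe has true coefficient ``beta``.

    Returns
    -------
    (methyl, traits) : the probe matrix and the augmented trait matrix, both
    indexed by sample id.
    """
    model.validate()
    for eff in model.planted:
        if eff.trait not in trait_matrix.columns:
            raise InvalidConfigError(
                f"planted effect references unknown trait {eff.trait!r}"
            )
    n_pairs = len(pair_table)
    n = 2 * n_pairs
    fam = rng.standard_normal((n_pairs, model.n_probes))
    fam = np.repeat(fam, 2, axis=0)  # pair order matches sample order below
    noise = rng.standard_normal((n, model.n_probes))
    raw = np.sqrt(model.family_var) * fam + np.sqrt(1 - model.family_var) * noise
    raw = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)

    sample_ids = np.ravel(pair_table[["sample_1", "sample_2"]].to_numpy())
    probes = [f"cg{i:08d}" for i in range(1, model.n_probes + 1)]
    methyl = pd.DataFrame(raw, index=pd.Index(sample_ids, name="sample_id"), columns=probes)

    traits = trait_matrix.copy()
    for eff in model.planted:
        if eff.probe not in methyl.columns:
            raise InvalidConfigError(f"planted probe {eff.probe!r} not generated")
        traits[eff.trait] = traits[eff.trait] + eff.beta * methyl[eff.probe].reindex(
            traits.index
        )
    return methyl, traits


def _probe_annotation(probes: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic probe annotation (chromosome, position, nearest gene)."""
    return pd.DataFrame(
        {
            "probe": probes,
            "chr": rng.integers(1, 23, size=len(probes)),
            "map_position": rng.integers(10_000, 200_000_000, size=len(probes)),
            "nearest_gene": [f"GENE{i + 1}" for i in range(len(probes))],
        }
    )


@dataclass
class SyntheticCohort:
    """A fully generated twin cohort with its ground-truth configuration."""

    pair_table: pd.DataFrame
    covariates: pd.DataFrame
    trait_matrix: pd.DataFrame
    peak_matrix: pd.DataFrame
    methyl_matrix: pd.DataFrame
    probe_annotation: pd.DataFrame
    truth: SimulationConfig

    def write(self, outdir) -> dict[str, str]:
        """Write all tables as TSV plus the truth config as YAML; returns paths."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "pairs.tsv": self.pair_table,
            "covariates.tsv": self.covariates,
            "traits.tsv": self.trait_matrix.reset_index(),
            "peaks.tsv": self.peak_matrix.reset_index(),
            "methylation.tsv": self.methyl_matrix.reset_index(),
            "probe_annotation.tsv": self.probe_annotation,
        }
        for name, df in tables.items():
            p = outdir / name
            df.to_csv(p, sep="\t", index=False)
            paths[name] = str(p)
        cfg = outdir / "truth.yaml"
        cfg.write_text(self.truth.to_yaml())
        paths["truth.yaml"] = str(cfg)
        return paths


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort from a validated configuration."""
    config.validate()
    pair_table = _make_pair_table(config.n_mz, config.n_dz)
    cov = simulate_covariates(pair_table, config.covariate_model, stage_rng(config.seed, "covariates"))

    cm = config.covariate_model
    rng_b = stage_rng(config.seed, "batch_effects")
    age_c = cov["age"].to_numpy() - cm.age_mean
    trait_cols = {}
    for spec in config.trait_specs:
        rng_t = stage_rng(config.seed, f"trait:{spec.name}")
        mz, dz = simulate_twin_trait(config.n_mz, config.n_dz, spec.a2, spec.c2, rng_t)
        core = np.concatenate([mz.ravel(), dz.ravel()])
        batch_fx = rng_b.normal(0.0, cm.batch_sd, size=cm.n_batches)
        y = core + cm.age_beta * age_c + batch_fx[cov["batch"].to_numpy() - 1]
        trait_cols[spec.name] = y
    traits = pd.DataFrame(
        trait_cols, index=pd.Index(cov["sample_id"].to_numpy(), name="sample_id")
    )

    peaks = simulate_peak_profiles(len(cov), config.peak_model, stage_rng(config.seed, "peaks"))
    peaks.index = pd.Index(cov["sample_id"].to_numpy(), name="sample_id")

    methyl, traits = simulate_methylation(
        pair_table, traits, config.methyl_model, stage_rng(config.seed, "methylation")
    )
    annot = _probe_annotation(list(methyl.columns), stage_rng(config.seed, "annotation"))
    return SyntheticCohort(
        pair_table=pair_table,
        covariates=cov,
        trait_matrix=traits,
        peak_matrix=peaks,
        methyl_matrix=methyl,
        probe_annotation=annot,
        truth=config,
    )
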