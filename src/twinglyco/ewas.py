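"""Epigenome-wide association with a family random intercept.

Each standardized methylation probe is regressed against a glycan trait with
a linear mixed model

    y = beta * m + gamma' covariates + u_family + eps,

where ``u_family`` is a family-level random intercept accounting for the
relatedness of co-twins.  Estimation is restricted maximum likelihood with a
single variance component (statsmodels MixedLM); the probe effect is reported
per SD of methylation on the standardized trait scale with a Wald p-value
against the normal reference.  Array-wide significance uses the Bonferroni
threshold ``alpha / n_probes``.

The trait outcomes are continuous, so the association model is linear; a
``dichotomize`` switch exists to median-split the outcome and fit the same
design by GEE logistic regression as a sensitivity analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "MethylationMatrix",
    "AlignmentError",
    "standardize_probes",
    "fit_random_intercept",
    "bonferroni_threshold",
    "run_ewas",
]

log = logging.getLogger(__name__)

#: Table layout for reported associations
ASSOCIATION_COLUMNS = [
    "probe",
    "chr",
    "map_position",
    "nearest_gene",
    "glycan",
    "beta",
    "se",
    "p",
    "significant",
]


class AlignmentError(ValueError):
    """Sample ids do not align across the EWAS inputs."""


@dataclass
class MethylationMatrix:
    """Standardized probe matrix (samples x probes) plus probe annotation."""

    values: pd.DataFrame
    annotation: pd.DataFrame | None = None

    @property
    def probes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def standardize_probes(raw: pd.DataFrame) -> MethylationMatrix:
    """Column-standardize probes to mean 0 and unit sample variance.

    Probes with fewer than two distinct values are dropped with a log entry;
    an all-constant matrix is an error.  The operation is idempotent.
    """
    sd = raw.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all probes are constant; nothing to standardize")
    if (~keep).any():
        log.warning("dropping %d constant probes", int((~keep).sum()))
    vals = raw.loc[:, keep]
    vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    return MethylationMatrix(values=vals)


def bonferroni_threshold(alpha: float, n_probes: int) -> tuple[float, float]:
    """Array-wide Bonferroni per-test threshold and its 1-significant-figure form.

    For alpha=0.05 over 24,641 probes this is 2.029e-6, reported as 2e-6.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    exact = alpha / n_probes
    rounded = float(f"{exact:.0e}")
    return exact, rounded


def _design_matrix(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    """Fixed-effect design from the covariate table (categoricals expanded)."""
    X = pd.DataFrame(index=index)
    X["const"] = 1.0
    if covariates is None:
        return X
    cov = covariates.loc[index]
    for col in cov.columns:
        if col in ("sample_id", "pair_id", "zygosity"):
            continue
        s = cov[col]
        if col in ("batch", "chip", "chip_position") or s.dtype == object:
            dummies = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[col] = s.astype(float)
    return X


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns that make the design rank-deficient (with a warning)."""
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return X
    keep: list[int] = []
    for j in range(arr.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(arr[:, trial]) == len(trial):
            keep.append(j)
    dropped = [c for i, c in enumerate(X.columns) if i not in keep]
    log.warning("dropping aliased design columns: %s", dropped)
    return X.iloc[:, keep]


def _model_based_se(X: np.ndarray, groups: np.ndarray, res) -> np.ndarray:
    """Model-based GLS standard errors, sqrt(diag((X' V^-1 X)^-1)).

    V is block-diagonal per family with sigma2*I + vfam*J blocks; for a
    group of size k, V^-1 = (I - vfam/(sigma2 + k*vfam) * J) / sigma2.
    This is the conventional mixed-model Wald SE and collapses exactly to
    the OLS SE when the family variance estimate hits the zero boundary.
    """
    s2 = float(res.scale)
    vfam = float(np.squeeze(res.cov_re))
    A = np.zeros((X.shape[1], X.shape[1]))
    order = np.argsort(groups, kind="mergesort")
    Xs, gs = X[order], np.asarray(groups)[order]
    start = 0
    for end in np.append(np.flatnonzero(gs[1:] != gs[:-1]) + 1, len(gs)):
        Xg = Xs[start:end]
        k = end - start
        colsum = Xg.sum(axis=0)
        A += (Xg.T @ Xg - (vfam / (s2 + k * vfam)) * np.outer(colsum, colsum)) / s2
        start = end
    return np.sqrt(np.diag(np.linalg.pinv(A)))


def fit_random_intercept(
    y: pd.Series | np.ndarray,
    m: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None,
    family_ids: pd.Series | np.ndarray,
    dichotomize: bool = False,
    t_reference: bool = False,
    full_output: bool = False,
):
    """Probe effect (beta, se, p) from the family random-intercept regression.

    ``y`` is the (continuous) trait, ``m`` the standardized probe values and
    ``family_ids`` the pair/family grouping of co-twins.  REML estimation;
    the Wald p uses the normal reference by default or, with
    ``t_reference=True``, a t distribution on the residual degrees of
    freedom.  ``dichotomize=True`` median-splits ``y`` and fits a
    cluster-robust logistic model instead (sensitivity mode).  With
    ``full_output=True`` the fitted family-intercept variance is appended to
    the returned tuple (linear model only).
    """
    y = pd.Series(np.asarray(y, dtype=float)).reset_index(drop=True)
    cov = covariates.reset_index(drop=True) if covariates is not None else None
    X = _design_matrix(cov, y.index)
    X.insert(1, "probe", np.asarray(m, dtype=float))
    X = _drop_aliased(X)
    groups = np.asarray(family_ids)
    ok = (y.notna() & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)).to_numpy()
    y, X, groups = y[ok], X[ok], groups[ok]

    if dichotomize:
        yb = (y > y.median()).astype(float)
        model = sm.GEE(
            yb, X, groups=groups, family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = model.fit()
        beta, se = float(res.params["probe"]), float(res.bse["probe"])
        p = 2.0 * float(stats.norm.sf(abs(beta / se)))
        return beta, se, p

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(y.to_numpy(), X.to_numpy(dtype=float), groups=groups).fit(reml=True)
    j = list(X.columns).index("probe")
    beta = float(res.fe_params[j])
    se = float(_model_based_se(X.to_numpy(dtype=float), groups, res)[j])
    z = beta / se
    if t_reference:
        df = len(y) - X.shape[1] - 1
        p = 2.0 * float(stats.t.sf(abs(z), df))
    else:
        p = 2.0 * float(stats.norm.sf(abs(z)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    if full_output:
        return beta, se, p, float(np.squeeze(res.cov_re))
    return beta, se, p


def run_ewas(
    trait_matrix: pd.DataFrame,
    traits: list[str],
    methyl: MethylationMatrix,
    covariates: pd.DataFrame | None = None,
    threshold: float | None = None,
    alpha: float = 0.05,
    dichotomize: bool = False,
) -> pd.DataFrame:
    """Per-(probe, trait) family random-intercept association table.

    Sample ids must align between ``trait_matrix``, the probe matrix and the
    covariate table (rows are intersected; ids present in the traits but not
    the probes raise :class:`AlignmentError` naming the offenders).  The
    result is sorted by p-value with annotation columns in the reported
    layout; ``significant`` flags p below the array-wide Bonferroni
    threshold (``alpha / n_probes`` unless ``threshold`` is given).
    """
    if not traits:
        raise ValueError("trait subset is empty")
    missing = [t for t in traits if t not in trait_matrix.columns]
    if missing:
        raise ValueError(f"unknown traits: {missing}")
    if not methyl.probes:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)

    trait_ids = set(trait_matrix.index)
    methyl_ids = set(methyl.values.index)
    only_traits = sorted(trait_ids - methyl_ids)
    if only_traits == sorted(trait_ids):
        raise AlignmentError(
            f"no overlapping sample ids; trait-only ids e.g. {only_traits[:5]}"
        )
    common = trait_matrix.index.intersection(methyl.values.index)
    if covariates is not None:
        cov = covariates.set_index("sample_id") if "sample_id" in covariates else covariates
        bad = [s for s in common if s not in cov.index]
        if bad:
            raise AlignmentError(f"samples missing covariates: {bad[:10]}")
        cov = cov.loc[common]
        fams = cov["pair_id"].to_numpy()
        cov_X = cov.drop(columns=[c for c in ("pair_id", "zygosity") if c in cov])
    else:
        raise AlignmentError("covariate table with pair_id is required for grouping")

    if threshold is None:
        threshold, _ = bonferroni_threshold(alpha, len(methyl.probes))

    annot = None
    if methyl.annotation is not None:
        annot = methyl.annotation.set_index("probe")

    records = []
    for probe in methyl.probes:
        mvals = methyl.values.loc[common, probe]
        for trait in traits:
            y = trait_matrix.loc[common, trait]
            try:
                beta, se, p = fit_random_intercept(
                    y, mvals, cov_X, fams, dichotomize=dichotomize
                )
            except (np.linalg.LinAlgError, ValueError) as err:
                log.warning("probe %s x trait %s failed: %s", probe, trait, err)
                continue
            rec = {
                "probe": probe,
                "glycan": trait,
                "beta": beta,
                "se": se,
                "p": p,
                "significant": p < threshold,
            }
            if annot is not None and probe in annot.index:
                rec["chr"] = annot.loc[probe, "chr"]
                rec["map_position"] = annot.loc[probe, "map_position"]
                rec["nearest_gene"] = annot.loc[probe, "nearest_gene"]
            records.append(rec)
    out = pd.DataFrame(records)
    if out.empty:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    for col in ("chr", "map_position", "nearest_gene"):
        if col not in out:
            out[col] = pd.NA
    out = out[ASSOCIATION_COLUMNS].sort_values("p", kind="mergesort").reset_index(drop=True)
    return out
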