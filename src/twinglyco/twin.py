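"""Classical twin-design variance decomposition (ACE model family).

The phenotypic variance of a trait measured on monozygotic (MZ) and dizygotic
(DZ) twin pairs is decomposed into additive genetic (A), shared/common
environmental (C) and unique environmental (E) components.  Under the equal
environment assumption each pair is bivariate normal with common variance
``vA + vC + vE`` and cross-twin covariance ``vA + vC`` (MZ) or
``0.5*vA + vC`` (DZ); MZ co-twins share all additive genetic influences, DZ
co-twins half of them.

Model fitting is by maximum likelihood over the raw variance components
(reported as standardized shares a2/c2/e2 summing to 1), with the submodels
AE, CE and E obtained by fixing components at zero.  The best submodel is
chosen by sequentially dropping factors from the full ACE model with a
likelihood-ratio test and, among the surviving models, taking the lowest AIC.
Confidence intervals are profile-likelihood intervals on the standardized
shares.

Because pairs are exchangeable and the likelihood depends on the data only
through the per-group sums ``x1^2 + x2^2`` and ``x1*x2``, all likelihood
evaluations are closed-form in those sufficient statistics; fits take
microseconds, which makes the design-power simulation cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import simulate_twin_trait

__all__ = [
    "DegenerateTraitError",
    "residualize",
    "icc",
    "twin_loglik",
    "TwinACEModel",
    "TwinACEResults",
    "ModelSelection",
    "select_best_model",
    "classify_heritability",
    "power_simulation",
    "PowerResult",
    "heritability_table",
]

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
#: chi2_1(0.95)/2 — profile log-likelihood drop defining a 95% interval
PROFILE_DROP = stats.chi2.ppf(0.95, 1) / 2.0

MODELS = ("ACE", "AE", "CE", "E")
_FREE = {"ACE": ("a", "c", "e"), "AE": ("a", "e"), "CE": ("c", "e"), "E": ("e",)}


class DegenerateTraitError(ValueError):
    """Trait with (near-)zero variance; cannot be standardized or fitted."""


# ---------------------------------------------------------------------------
# covariate adjustment and intra-class correlation


def residualize(values: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """Least-squares residuals of a trait on age and batch, standardized.

    ``covariates`` must contain ``age`` and ``batch`` indexed like ``values``
    (batch is treated as categorical).  The residuals are rescaled to mean 0
    and unit variance, which is the scale on which the twin likelihood and
    the reported variance shares live.
    """
    y = np.asarray(values, dtype=float)
    if np.nanstd(y) < 1e-12:
        raise DegenerateTraitError(f"trait {values.name!r} is constant")
    X = pd.get_dummies(
        covariates.loc[values.index, ["age", "batch"]].astype({"batch": "category"}),
        columns=["batch"],
        drop_first=True,
        dtype=float,
    )
    X.insert(0, "const", 1.0)
    ok = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    resid = np.full_like(y, np.nan)
    beta, *_ = np.linalg.lstsq(X.to_numpy()[ok], y[ok], rcond=None)
    resid[ok] = y[ok] - X.to_numpy()[ok] @ beta
    sd = resid[ok].std()
    if sd < 1e-12:
        raise DegenerateTraitError(f"trait {values.name!r} degenerate after adjustment")
    resid = (resid - resid[ok].mean()) / sd
    return pd.Series(resid, index=values.index, name=values.name)


def icc(pairs: np.ndarray, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Intra-class correlation of one zygosity group by double entry.

    Each of the n pairs is entered twice, once in each order, and the Pearson
    correlation of the doubled vectors is taken (the twin-literature
    convention).  The confidence interval uses the Fisher z transform with
    effective sample size equal to the number of pairs.
    """
    pairs = np.asarray(pairs, dtype=float)
    pairs = pairs[np.isfinite(pairs).all(axis=1)]
    n = len(pairs)
    if n < 3:
        raise DegenerateTraitError(f"need >= 3 complete pairs, got {n}")
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    r = float(np.corrcoef(x, y)[0, 1])
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    else:
        lo, hi = -1.0, 1.0
    return r, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# likelihood


def _suffstats(pairs: np.ndarray) -> tuple[int, float, float]:
    """(n_pairs, sum of x1^2+x2^2, sum of x1*x2) for one zygosity group."""
    pairs = np.asarray(pairs, dtype=float)
    pairs = pairs[np.isfinite(pairs).all(axis=1)]
    return len(pairs), float((pairs**2).sum()), float((pairs[:, 0] * pairs[:, 1]).sum())


def _group_loglik(n: int, sxx: float, sxy: float, v: float, c: float) -> float:
    det = v * v - c * c
    if v <= 0 or det <= 0:
        return -np.inf
    return -n * _LOG2PI - 0.5 * n * np.log(det) - (v * sxx - 2.0 * c * sxy) / (2.0 * det)


def twin_loglik(
    mz_pairs: np.ndarray, dz_pairs: np.ndarray, a2: float, c2: float, e2: float
) -> float:
    """Joint log-likelihood of MZ and DZ pairs under raw variances (a2,c2,e2).

    Returns ``-inf`` (optimizer-safe) when the implied 2x2 covariance matrix
    is not positive definite.
    """
    if min(a2, c2, e2) < 0:
        return -np.inf
    v = a2 + c2 + e2
    n1, sxx1, sxy1 = _suffstats(mz_pairs)
    n2, sxx2, sxy2 = _suffstats(dz_pairs)
    return _group_loglik(n1, sxx1, sxy1, v, a2 + c2) + _group_loglik(
        n2, sxx2, sxy2, v, 0.5 * a2 + c2
    )


# ---------------------------------------------------------------------------
# model objects


@dataclass
class TwinACEResults:
    """Fitted variance decomposition for one trait and one submodel."""

    model: str
    a2: float
    c2: float
    e2: float
    raw: dict[str, float]
    loglik: float
    aic: float
    n_mz: int
    n_dz: int
    trait: str | None = None
    _model_obj: "TwinACEModel" = field(default=None, repr=False)

    @property
    def h2(self) -> float | None:
        """Heritability (the additive share); None when the model lacks A."""
        return self.a2 if "a" in _FREE[self.model] else None

    @property
    def df_model(self) -> int:
        return len(_FREE[self.model])

    def conf_int(self, component: str, level: float = 0.95) -> tuple[float, float]:
        """Profile-likelihood interval for a standardized share ('a2','c2','e2')."""
        return self._model_obj.profile_ci(self, component, level=level)

    def summary(self) -> str:
        lines = [
            f"Twin ACE decomposition — model {self.model}"
            + (f", trait {self.trait}" if self.trait else ""),
            f"  pairs: {self.n_mz} MZ, {self.n_dz} DZ",
            f"  loglik {self.loglik:.3f}   AIC {self.aic:.3f}",
        ]
        for comp, share in (("a2", self.a2), ("c2", self.c2), ("e2", self.e2)):
            if comp[0] in _FREE[self.model]:
                lo, hi = self.conf_int(comp)
                lines.append(f"  {comp} = {share:.3f} [{lo:.3f}, {hi:.3f}]")
            else:
                lines.append(f"  {comp} = 0 (fixed)")
        return "\n".join(lines)


class TwinACEModel:
    """Maximum-likelihood ACE model for one trait on MZ/DZ paired values.

    Parameters
    ----------
    mz_pairs, dz_pairs : array-like of shape (n, 2)
        Adjusted, standardized trait values of the two co-twins; pairs with
        a missing member are excluded from the likelihood.
    trait : optional trait name carried into the results.
    """

    # fixed deterministic starting shares (a2, c2, e2)
    _STARTS = ((1 / 3, 1 / 3, 1 / 3), (0.6, 0.1, 0.3), (0.1, 0.6, 0.3))

    def __init__(self, mz_pairs, dz_pairs, trait: str | None = None):
        self.trait = trait
        self._mz = np.asarray(mz_pairs, dtype=float).reshape(-1, 2)
        self._dz = np.asarray(dz_pairs, dtype=float).reshape(-1, 2)
        self._ss_mz = _suffstats(self._mz)
        self._ss_dz = _suffstats(self._dz)
        self.n_mz, self.n_dz = self._ss_mz[0], self._ss_dz[0]
        n = self.n_mz + self.n_dz
        if n == 0:
            raise DegenerateTraitError("no complete twin pairs")
        self._vtot = (self._ss_mz[1] + self._ss_dz[1]) / (2 * n)

    @classmethod
    def from_dataframe(
        cls,
        pairs: pd.DataFrame,
        value_1: str = "value_1",
        value_2: str = "value_2",
        zygosity: str = "zygosity",
        trait: str | None = None,
    ) -> "TwinACEModel":
        mz = pairs.loc[pairs[zygosity] == "MZ", [value_1, value_2]].to_numpy()
        dz = pairs.loc[pairs[zygosity] == "DZ", [value_1, value_2]].to_numpy()
        return cls(mz, dz, trait=trait)

    # -- likelihood ---------------------------------------------------------
    def loglik(self, a2: float, c2: float, e2: float) -> float:
        """Log-likelihood at raw variance components."""
        if min(a2, c2, e2) < 0:
            return -np.inf
        v = a2 + c2 + e2
        n1, sxx1, sxy1 = self._ss_mz
        n2, sxx2, sxy2 = self._ss_dz
        return _group_loglik(n1, sxx1, sxy1, v, a2 + c2) + _group_loglik(
            n2, sxx2, sxy2, v, 0.5 * a2 + c2
        )

    def _loglik_shares(self, ta: float, tc: float) -> float:
        """Profile log-likelihood over the total variance at fixed shares."""
        te = 1.0 - ta - tc
        if min(ta, tc) < 0 or te <= 0:
            return -np.inf
        n1, sxx1, sxy1 = self._ss_mz
        n2, sxx2, sxy2 = self._ss_dz
        N = n1 + n2
        Q = 0.0
        logdet_r = 0.0
        for n, sxx, sxy, r in (
            (n1, sxx1, sxy1, ta + tc),
            (n2, sxx2, sxy2, 0.5 * ta + tc),
        ):
            if n == 0:
                continue
            d = 1.0 - r * r
            if d <= 0:
                return -np.inf
            Q += (sxx - 2.0 * r * sxy) / d
            logdet_r += 0.5 * n * np.log(d)
        if Q <= 0:
            return -np.inf
        vhat = Q / (2.0 * N)
        return -N * _LOG2PI - N * np.log(vhat) - logdet_r - N

    # -- fitting ------------------------------------------------------------
    def fit(self, model: str = "ACE") -> TwinACEResults:
        """Constrained ML fit of one submodel (ACE, AE, CE or E)."""
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}")
        free = _FREE[model]
        scale = max(self._vtot, 1e-12)

        def neg(params: np.ndarray) -> float:
            comp = dict.fromkeys("ace", 0.0)
            for name, val in zip(free, params):
                comp[name] = val
            return -self.loglik(comp["a"], comp["c"], comp["e"])

        bounds = [(0.0, 20.0 * scale)] * len(free)
        bounds[-1] = (1e-10 * scale, 20.0 * scale)  # e variance strictly > 0
        best = None
        for start in self._STARTS:
            shares = dict(zip("ace", start))
            x0 = np.array([max(shares[f], 0.05) * scale for f in free])
            res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"model {model}: optimizer failed to converge")
        raw = dict.fromkeys("ace", 0.0)
        for name, val in zip(free, best.x):
            raw[name] = float(val)
        total = sum(raw.values())
        shares = {k: v / total for k, v in raw.items()}
        ll = -float(best.fun)
        return TwinACEResults(
            model=model,
            a2=shares["a"],
            c2=shares["c"],
            e2=shares["e"],
            raw=raw,
            loglik=ll,
            aic=-2.0 * ll + 2.0 * len(free),
            n_mz=self.n_mz,
            n_dz=self.n_dz,
            trait=self.trait,
            _model_obj=self,
        )

    def fit_all(self) -> dict[str, TwinACEResults]:
        return {m: self.fit(m) for m in MODELS}

    def select(self, alpha: float = 0.05) -> "ModelSelection":
        return select_best_model(self.fit_all(), lrt_alpha=alpha)

    # -- profile confidence intervals ---------------------------------------
    def _profile_loglik(self, result: TwinACEResults, component: str, t: float) -> float:
        """Max log-likelihood with the given standardized share fixed at t."""
        free = _FREE[result.model]
        comp = component[0]
        if comp not in free:
            raise ValueError(f"{component} is fixed at 0 under model {result.model}")
        eps = 1e-9
        if len(free) == 2:
            other = [f for f in free if f != comp][0]
            full = dict.fromkeys("ace", 0.0)
            full[comp] = t
            full[other] = 1.0 - t
            return self._loglik_shares(full["a"], full["c"])
        # ACE: optimize the split of the remaining mass between the other two
        others = [f for f in free if f != comp]

        def prof(s: float) -> float:
            full = dict.fromkeys("ace", 0.0)
            full[comp] = t
            full[others[0]] = s
            full[others[1]] = 1.0 - t - s
            return self._loglik_shares(full["a"], full["c"])

        hi = max(1.0 - t - eps, 0.0)
        if hi <= 0:
            return prof(0.0)
        res = optimize.minimize_scalar(
            lambda s: -prof(s), bounds=(0.0, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        return -float(res.fun)

    def profile_ci(
        self, result: TwinACEResults, component: str, level: float = 0.95
    ) -> tuple[float, float]:
        """Profile-likelihood interval for a standardized share, within [0,1].

        The interval collects share values whose profiled log-likelihood lies
        within ``chi2_1(level)/2`` of the maximum.
        """
        drop = stats.chi2.ppf(level, 1) / 2.0
        comp = component[0]
        if comp not in _FREE[result.model]:
            raise ValueError(f"{component} is fixed at 0 under model {result.model}")
        if len(_FREE[result.model]) == 1:
            return (1.0, 1.0)  # E model: the e2 share is identically 1
        that = {"a": result.a2, "c": result.c2, "e": result.e2}[comp]
        llmax = self._profile_loglik(result, component, min(max(that, 1e-9), 1 - 1e-9))
        llmax = max(llmax, result.loglik)

        def g(t: float) -> float:
            return self._profile_loglik(result, component, t) - (llmax - drop)

        lo_end, hi_end = 1e-9, 1.0 - 1e-9
        that_c = min(max(that, lo_end), hi_end)
        if not np.isfinite(llmax):
            log.warning("flat likelihood profiling %s; returning [0, 1]", component)
            return (0.0, 1.0)
        # lower bound
        if g(lo_end) >= 0:
            lo = 0.0
        else:
            lo = float(optimize.brentq(g, lo_end, that_c, xtol=1e-6))
        # upper bound
        if g(hi_end) >= 0:
            hi = 1.0
        else:
            hi = float(optimize.brentq(g, that_c, hi_end, xtol=1e-6))
        return (lo, hi)


# ---------------------------------------------------------------------------
# model selection


@dataclass
class ModelSelection:
    """Outcome of the sequential-drop model search over ACE/AE/CE/E."""

    fits: dict[str, TwinACEResults]
    lrt_pvalues: dict[str, float]
    surviving: tuple[str, ...]
    best_model: str
    trace: list[str]

    @property
    def best(self) -> TwinACEResults:
        return self.fits[self.best_model]

    def summary(self) -> str:
        lines = ["Model selection (sequential drops from ACE):"]
        lines += [f"  {line}" for line in self.trace]
        lines.append(f"  chosen: {self.best_model}")
        return "\n".join(lines)


def select_best_model(
    fits: dict[str, TwinACEResults], lrt_alpha: float = 0.05
) -> ModelSelection:
    """Choose the best submodel by sequential LRT drops plus AIC.

    Starting from the full ACE model, dropping C (-> AE), A (-> CE) or both
    (-> E) is accepted when the likelihood-ratio p-value is at or above
    ``lrt_alpha`` (chi-square reference, df = number of parameters removed).
    Among the surviving models the lowest AIC wins; exact AIC ties go to the
    model with fewer free parameters (and to AE over CE).
    """
    missing = [m for m in MODELS if m not in fits]
    if missing:
        raise ValueError(f"missing submodel fits: {missing}")
    ll = {m: fits[m].loglik for m in MODELS}
    pvals = {}
    trace = []
    surviving = ["ACE"]
    for sub, df in (("AE", 1), ("CE", 1), ("E", 2)):
        stat = max(0.0, 2.0 * (ll["ACE"] - ll[sub]))
        p = float(stats.chi2.sf(stat, df))
        pvals[sub] = p
        accepted = p >= lrt_alpha
        if accepted:
            surviving.append(sub)
        trace.append(
            f"ACE -> {sub}: LRT stat {stat:.4f} (df {df}), p {p:.4g} "
            f"{'drop accepted' if accepted else 'drop rejected'}"
        )
    order = {"E": 0, "AE": 1, "CE": 2, "ACE": 3}  # fewer params first, AE before CE
    best = min(surviving, key=lambda m: (fits[m].aic, fits[m].df_model, order[m]))
    trace.append(
        "AIC among surviving: "
        + ", ".join(f"{m} {fits[m].aic:.2f}" for m in surviving)
    )
    return ModelSelection(
        fits=fits,
        lrt_pvalues=pvals,
        surviving=tuple(surviving),
        best_model=best,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# heritability classification


@dataclass(frozen=True)
class HeritabilityClass:
    trait: str
    label: str  # "low" | "high"
    basis: str


def classify_heritability(
    decompositions: list[TwinACEResults] | dict[str, TwinACEResults],
    threshold: float = 0.35,
) -> list[HeritabilityClass]:
    """Split traits into low/high heritability classes.

    A trait is *low* when its best model has no additive component (CE or E)
    or when its additive share satisfies ``a2 <= threshold`` (inclusive: a
    trait sitting exactly at the threshold is counted low); otherwise *high*.
    """
    if isinstance(decompositions, dict):
        items = [(k, v) for k, v in decompositions.items()]
    else:
        items = [(d.trait or f"trait{i}", d) for i, d in enumerate(decompositions)]
    out = []
    for name, d in items:
        if d.h2 is None:
            out.append(HeritabilityClass(name, "low", "no additive component"))
        elif d.h2 <= threshold:
            out.append(HeritabilityClass(name, "low", f"h2={d.h2:.3f}<={threshold}"))
        else:
            out.append(HeritabilityClass(name, "high", f"h2={d.h2:.3f}>{threshold}"))
    return out


# ---------------------------------------------------------------------------
# design power


@dataclass(frozen=True)
class PowerResult:
    power: float
    se: float
    n_reps: int
    rejections: int
    n_mz: int
    n_dz: int
    a2: float
    c2: float
    alpha: float


def power_simulation(
    n_mz: int,
    n_dz: int,
    a2: float,
    c2: float,
    alpha: float = 0.05,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    mixture: bool = False,
) -> PowerResult:
    """Monte-Carlo power of the likelihood-ratio test for the additive component.

    Each replicate simulates ``n_mz`` MZ and ``n_dz`` DZ standardized pairs
    with the given true shares and tests the additive component by comparing
    the best A-containing model against its A-free counterpart: the shared
    environment is first dropped from the full model by a 1-df LRT at
    ``alpha`` (accepted drop -> AE vs E, rejected -> ACE vs CE), and the
    replicate counts as a rejection when the resulting 1-df additive LRT
    p-value is below ``alpha``.  With ``mixture=True`` the boundary-corrected
    50:50 mixture reference (half the chi-square tail) is used for the
    additive test instead of the plain chi-square; the plain reference is the
    study-era convention and the default.

    Returns the rejection fraction with its binomial Monte-Carlo SE.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable estimate")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rejections = 0
    for _ in range(n_reps):
        mz, dz = simulate_twin_trait(n_mz, n_dz, a2, c2, rng)
        model = TwinACEModel(mz, dz)
        ll = {m: model.fit(m).loglik for m in MODELS}
        drop_c = max(0.0, 2.0 * (ll["ACE"] - ll["AE"]))
        if stats.chi2.sf(drop_c, 1) >= alpha:  # C dropped: best A-model is AE
            stat = max(0.0, 2.0 * (ll["AE"] - ll["E"]))
        else:
            stat = max(0.0, 2.0 * (ll["ACE"] - ll["CE"]))
        p = float(stats.chi2.sf(stat, 1))
        if mixture:
            p = 0.5 * p if stat > 0 else 1.0
        if p < alpha:
            rejections += 1
    power = rejections / n_reps
    se = float(np.sqrt(power * (1.0 - power) / n_reps))
    return PowerResult(power, se, n_reps, rejections, n_mz, n_dz, a2, c2, alpha)


# ---------------------------------------------------------------------------
# per-trait cohort driver


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _fmt_ci(est: float, ci: tuple[float, float]) -> str:
    return f"{est:.2f}[{ci[0]:.2f},{ci[1]:.2f}]"


def heritability_table(
    trait_matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    threshold: float = 0.35,
    adjust: bool = True,
) -> pd.DataFrame:
    """Full per-trait heritability analysis for a twin cohort.

    ``trait_matrix`` is samples x traits (indexed by sample id);
    ``covariates`` must carry ``sample_id``, ``pair_id``, ``zygosity``,
    ``age`` and ``batch``.  Each trait is adjusted for age and batch by
    residualization, decomposed by the ACE model family with model selection,
    and classified as low/high heritability.  Returns one row per trait with
    unadjusted group means/SDs, double-entry ICCs, the chosen model, the
    standardized components with profile CIs, and numeric columns for
    downstream use.  Degenerate traits are skipped with a log entry.
    """
    cov = covariates.set_index("sample_id")
    rows = []
    pair_info = cov[["pair_id", "zygosity"]]
    for trait in trait_matrix.columns:
        raw = trait_matrix[trait]
        try:
            adj = residualize(raw, cov) if adjust else raw
        except DegenerateTraitError as err:
            log.warning("skipping trait %s: %s", trait, err)
            continue
        df = pd.DataFrame({"value": adj, "raw": raw}).join(pair_info)
        grouped = {}
        stats_raw = {}
        for zyg in ("MZ", "DZ"):
            sub = df[df["zygosity"] == zyg]
            stats_raw[zyg] = (sub["raw"].mean(), sub["raw"].std())
            pv = sub.groupby("pair_id")["value"].apply(list)
            arr = np.array([v for v in pv if len(v) == 2], dtype=float)
            grouped[zyg] = arr
        model = TwinACEModel(grouped["MZ"], grouped["DZ"], trait=trait)
        sel = model.select(alpha=alpha)
        best = sel.best
        icc_mz, ci_mz = icc(grouped["MZ"])
        icc_dz, ci_dz = icc(grouped["DZ"])
        comps = {}
        for comp, share in (("a2", best.a2), ("c2", best.c2), ("e2", best.e2)):
            if comp[0] in _FREE[best.model]:
                comps[comp] = _fmt_ci(share, best.conf_int(comp))
            else:
                comps[comp] = ""
        label = classify_heritability([best], threshold=threshold)[0].label
        rows.append(
            {
                "trait": trait,
                "mz_mean_sd": f"{stats_raw['MZ'][0]:.2f}({stats_raw['MZ'][1]:.2f})",
                "icc_mz": _fmt_ci(icc_mz, ci_mz),
                "dz_mean_sd": f"{stats_raw['DZ'][0]:.2f}({stats_raw['DZ'][1]:.2f})",
                "icc_dz": _fmt_ci(icc_dz, ci_dz),
                "best_model": best.model,
                "A": comps["a2"],
                "C": comps["c2"],
                "E": comps["e2"],
                "a2": best.a2 if best.h2 is not None else np.nan,
                "c2": best.c2 if "c" in _FREE[best.model] else np.nan,
                "e2": best.e2,
                "loglik": best.loglik,
                "aic": best.aic,
                "icc_mz_value": icc_mz,
                "icc_dz_value": icc_dz,
                "heritability_class": label,
            }
        )
    return pd.DataFrame(rows)
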