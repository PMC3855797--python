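"""Derived IgG glycan traits from the 24-peak UPLC profile.

The 24 chromatographic peaks (GP1-GP24, each expressed as % of total
integrated area) are mapped to structural features — core fucose (F),
bisecting GlcNAc (B), galactose count (G0/G1/G2) and sialic-acid count
(S1/S2) — by an editable annotation table.  Derived traits are ratios of
feature-group sums, written in a small expression grammar, e.g.::

    FGS / (FG + FGS)        sialylation of fucosylated galactosylated glycans
    FBn / Fn                bisecting among fucosylated, on the neutral basis

Grammar for a group token (spaces ignored):

* leading ``F`` — core-fucosylated; ``B`` — bisecting GlcNAc.  A token
  naming either constrains the other to absent (``FG`` is fucosylated
  non-bisecting, ``Bn`` bisecting non-fucosylated) unless a ``total``
  modifier lifts the bisecting constraint (``Ftotal``, ``Fn total``);
  a token naming neither (``G0n``) spans the whole feature stratum
* ``G0``/``G1``/``G2`` — exact galactose count; bare ``G`` means >= 1
* ``S1``/``S2`` — exact sialic-acid count; bare ``S`` or ``Stotal`` means
  >= 1; a token with no S part selects neutral (asialylated) structures
* trailing ``n`` — evaluate on the neutral-normalized basis (each neutral
  peak as % of the summed neutral peaks); a trailing ``total`` again
  unconstrains bisecting
* when no G part is given: galactose is unconstrained if the token carries
  an S part or the neutral basis, otherwise it means agalactosylated
  (so ``F`` is FA2-type while ``Fn`` is all fucosylated neutral glycans)
* ``GPk`` / ``GPkn`` — a single peak, raw or neutral-normalized

Only the anchored assignments (GP4=FA2, GP8/GP9=FA2G1, GP14=FA2G2,
GP21=A2G2S2) are fixed by the study text; the rest of the shipped annotation
is the conventional IgG UPLC assignment and is flagged as such in the file.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PeakAnnotation",
    "TraitDefinition",
    "TraitDefinitionError",
    "load_annotation",
    "load_definitions",
    "default_annotation",
    "default_definitions",
    "neutral_percentages",
    "group_sum",
    "evaluate_trait",
    "compute_all_traits",
]

log = logging.getLogger(__name__)


class TraitDefinitionError(ValueError):
    """A trait definition that cannot be evaluated against the annotation."""


@dataclass(frozen=True)
class PeakAnnotation:
    """Structural features of one UPLC peak."""

    peak_id: str
    structure_code: str
    fucosylated: bool
    bisecting: bool
    gal_count: int
    sial_count: int
    conventional: bool = True

    @property
    def neutral(self) -> bool:
        return self.sial_count == 0


@dataclass(frozen=True)
class TraitDefinition:
    """A derived trait: numerator / denominator expression on a scale."""

    name: str
    numerator: str
    denominator: str = "1"
    scale: str = "ratio"  # ratio | percent | permille | raw

    _SCALE_FACTOR = {"ratio": 1.0, "raw": 1.0, "percent": 100.0, "permille": 1000.0}

    @property
    def scale_factor(self) -> float:
        try:
            return self._SCALE_FACTOR[self.scale]
        except KeyError:
            raise TraitDefinitionError(
                f"trait {self.name!r}: unknown scale {self.scale!r}"
            ) from None


_TOKEN_RE = re.compile(
    r"^(?P<f>F)?(?P<ftot>total)?(?P<b>B)?"
    r"(?:G(?P<g>[012])?)?"
    r"(?:S(?P<s>[12])?(?P<stot>total)?)?"
    r"(?P<n>n)?(?P<ntot>total)?$"
)
_PEAK_RE = re.compile(r"^(?P<peak>GP\d+)(?P<n>n)?$")


@dataclass(frozen=True)
class _Predicate:
    """Feature conditions selecting a set of peaks, with an evaluation basis."""

    fucosylated: bool | None
    bisecting: bool | None
    gal: tuple[int, ...] | None
    sial: tuple[int, ...] | None
    neutral_basis: bool
    peak: str | None = None

    def matches(self, a: PeakAnnotation) -> bool:
        if self.peak is not None:
            return a.peak_id == self.peak
        if self.fucosylated is not None and a.fucosylated != self.fucosylated:
            return False
        if self.bisecting is not None and a.bisecting != self.bisecting:
            return False
        if self.gal is not None and a.gal_count not in self.gal:
            return False
        if self.sial is not None and a.sial_count not in self.sial:
            return False
        return True


def parse_token(token: str) -> _Predicate:
    """Parse one group token of the trait grammar into a peak predicate."""
    tok = token.replace(" ", "").replace("‰", "")
    if not tok:
        raise TraitDefinitionError("empty group token")
    m = _PEAK_RE.match(tok)
    if m:
        return _Predicate(None, None, None, None, bool(m.group("n")), peak=m.group("peak"))
    m = _TOKEN_RE.match(tok)
    if not m or not any(m.group(g) for g in ("f", "b", "g", "s", "n", "stot")):
        raise TraitDefinitionError(f"cannot parse group token {token!r}")
    # token text like "G" or "S" with no captured digit still constrains
    has_g = "G" in tok
    has_s = "S" in tok
    has_f = m.group("f") is not None
    has_b = m.group("b") is not None
    neutral_basis = m.group("n") is not None
    # F and B are constrained only when the token mentions either of them:
    # "FG" is fucosylated non-bisecting, "Bn" is bisecting non-fucosylated,
    # while bare gal groups like "G0n" span the whole feature stratum.
    fuc: bool | None = True if has_f else (False if has_b else None)
    bisecting: bool | None = True if has_b else (False if has_f else None)
    if m.group("ftot") is not None or m.group("ntot") is not None:
        bisecting = None

    if has_g:
        g = m.group("g")
        gal: tuple[int, ...] | None = (int(g),) if g is not None else (1, 2)
    elif has_s or neutral_basis:
        gal = None  # unconstrained
    else:
        gal = (0,)

    if has_s:
        s = m.group("s")
        sial: tuple[int, ...] | None = (int(s),) if s is not None else (1, 2)
    else:
        sial = (0,)
    if neutral_basis and has_s:
        raise TraitDefinitionError(
            f"token {token!r}: sialylated group on the neutral basis"
        )
    return _Predicate(fuc, bisecting, gal, sial, neutral_basis)


def _parse_expression(expr: str) -> list[_Predicate]:
    expr = expr.strip()
    if expr in ("1", ""):
        return []
    expr = expr.strip("()")
    return [parse_token(t) for t in expr.split("+")]


# ---------------------------------------------------------------------------
# shipped annotation / definitions


def load_annotation(path_or_buf) -> dict[str, PeakAnnotation]:
    """Load a peak annotation TSV (peak_id, structure_code, F/B/G/S columns)."""
    df = pd.read_csv(path_or_buf, sep="\t")
    ann = {}
    for _, r in df.iterrows():
        a = PeakAnnotation(
            peak_id=r["peak_id"],
            structure_code=r["structure_code"],
            fucosylated=bool(r["fucosylated"]),
            bisecting=bool(r["bisecting"]),
            gal_count=int(r["gal_count"]),
            sial_count=int(r["sial_count"]),
            conventional=bool(r.get("conventional", True)),
        )
        if a.peak_id in ann:
            raise TraitDefinitionError(f"duplicate peak id {a.peak_id}")
        ann[a.peak_id] = a
    return ann


def load_definitions(path_or_buf) -> list[TraitDefinition]:
    """Load a trait-definition TSV (name, numerator, denominator, scale)."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str).fillna("1")
    defs = [
        TraitDefinition(r["name"], r["numerator"], r["denominator"], r["scale"])
        for _, r in df.iterrows()
    ]
    names = [d.name for d in defs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise TraitDefinitionError(f"duplicate trait names: {sorted(dupes)}")
    return defs


def _data_file(name: str):
    return resources.files("twinglyco").joinpath("data", name)


def default_annotation() -> dict[str, PeakAnnotation]:
    with resources.as_file(_data_file("peak_annotation.tsv")) as p:
        return load_annotation(p)


def default_definitions() -> list[TraitDefinition]:
    with resources.as_file(_data_file("trait_definitions.tsv")) as p:
        return load_definitions(p)


# ---------------------------------------------------------------------------
# evaluation


def neutral_percentages(
    peak_matrix: pd.DataFrame, annotation: dict[str, PeakAnnotation]
) -> pd.DataFrame:
    """Neutral peaks renormalized to % of the summed neutral (asialylated) peaks.

    Returns one ``GPkn`` column per neutral peak; samples whose neutral sum is
    non-positive get missing values and are reported in the log.
    """
    _check_annotation(peak_matrix, annotation)
    neutral = [p for p in peak_matrix.columns if annotation[p].neutral]
    total = peak_matrix[neutral].sum(axis=1)
    bad = total <= 0
    if bad.any():
        log.warning("neutral sum <= 0 for %d samples; traits set missing", int(bad.sum()))
        total = total.where(~bad)
    out = peak_matrix[neutral].div(total, axis=0) * 100.0
    out.columns = [f"{p}n" for p in neutral]
    return out


def _check_annotation(peak_matrix, annotation):
    missing = [p for p in peak_matrix.columns if p not in annotation]
    if missing:
        raise TraitDefinitionError(f"annotation missing for peaks {missing}")


def _basis_values(
    predicate: _Predicate,
    peak_matrix: pd.DataFrame,
    neutral_pct: pd.DataFrame,
    annotation: dict[str, PeakAnnotation],
) -> pd.Series:
    if predicate.peak is not None:
        col = predicate.peak
        if predicate.neutral_basis:
            name = f"{col}n"
            if name not in neutral_pct.columns:
                raise TraitDefinitionError(f"{col} is not a neutral peak")
            return neutral_pct[name]
        if col not in peak_matrix.columns:
            raise TraitDefinitionError(f"unknown peak {col}")
        return peak_matrix[col]
    peaks = [p for p in peak_matrix.columns if predicate.matches(annotation[p])]
    if not peaks:
        raise TraitDefinitionError(f"predicate selects no peaks: {predicate}")
    if predicate.neutral_basis:
        return neutral_pct[[f"{p}n" for p in peaks]].sum(axis=1, min_count=1)
    return peak_matrix[peaks].sum(axis=1)


def group_sum(
    expression: str,
    peak_matrix: pd.DataFrame,
    annotation: dict[str, PeakAnnotation],
    neutral_pct: pd.DataFrame | None = None,
) -> pd.Series:
    """Sum of the peaks selected by a ``+``-joined group expression."""
    if neutral_pct is None:
        neutral_pct = neutral_percentages(peak_matrix, annotation)
    preds = _parse_expression(expression)
    if not preds:
        return pd.Series(1.0, index=peak_matrix.index)
    return sum(_basis_values(p, peak_matrix, neutral_pct, annotation) for p in preds)


def evaluate_trait(
    definition: TraitDefinition,
    peak_matrix: pd.DataFrame,
    annotation: dict[str, PeakAnnotation],
    neutral_pct: pd.DataFrame | None = None,
) -> pd.Series:
    """Evaluate one derived trait for every sample.

    Division by zero yields a missing value (with a logged warning), not an
    exception, so cohort-level stages can drop the affected samples.
    """
    if neutral_pct is None:
        neutral_pct = neutral_percentages(peak_matrix, annotation)
    num = group_sum(definition.numerator, peak_matrix, annotation, neutral_pct)
    den = group_sum(definition.denominator, peak_matrix, annotation, neutral_pct)
    zero = den == 0
    if zero.any():
        log.warning(
            "trait %s: denominator 0 for %d samples, set missing",
            definition.name,
            int(zero.sum()),
        )
        den = den.where(~zero)
    return (num / den * definition.scale_factor).rename(definition.name)


def compute_all_traits(
    peak_matrix: pd.DataFrame,
    annotation: dict[str, PeakAnnotation] | None = None,
    definitions: list[TraitDefinition] | None = None,
) -> pd.DataFrame:
    """Evaluate a full trait panel.

    With ``definitions`` None the shipped default panel (the 76 study traits)
    is used; with an explicitly empty list only the 24 directly measured
    peaks are returned.
    """
    if annotation is None:
        annotation = default_annotation()
    if definitions is None:
        definitions = default_definitions()
    _check_annotation(peak_matrix, annotation)
    if not definitions:
        return peak_matrix.copy()
    npct = neutral_percentages(peak_matrix, annotation)
    cols = [evaluate_trait(d, peak_matrix, annotation, npct) for d in definitions]
    out = pd.concat(cols, axis=1)
    log.info("computed %d traits for %d samples", out.shape[1], out.shape[0])
    return out
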