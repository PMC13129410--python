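"""Conversion of heterogeneous reported statistics to correlation-scale effect sizes.

Primary studies on status signalling report their evidence in incompatible
currencies: Pearson correlations, dark/light group means with SDs and sample
sizes, t statistics, omnibus F statistics, and chi-square statistics from
contingency tables.  This module converts each of them to a signed
correlation-scale effect size ``r`` with a large-sample sampling variance
``v`` so they can enter a single meta-analysis.

Two conversion variants are provided for the means-SD-n route: the corrected
pooled-SD standardized difference, and an erroneous variant that reproduces a
missing pair of parentheses in the denominator (division applied to the last
summand only instead of the whole sum).  The erroneous variant exists solely
so its downstream consequences can be quantified; nothing else uses it.

Unsigned statistics (F, chi-square) carry no direction: their sign must be
assigned from the reported direction of the underlying relationship, and
records whose direction is unknown are flagged and excluded from model fits
by default rather than silently treated as positive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm


class Origin(str, enum.Enum):
    """Statistic class a correlation-scale effect was derived from."""

    PEARSON_R = "pearson_r"
    MEANS_SD_N = "means_sd_n"
    T_VALUE = "t_value"
    F_VALUE = "F_value"
    CHI2_VALUE = "chi2_value"


#: origins whose statistic is inherently unsigned
UNSIGNED_ORIGINS = frozenset({Origin.F_VALUE, Origin.CHI2_VALUE})


class Direction(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class SignSource(str, enum.Enum):
    INHERENT = "inherent"
    ASSIGNED_FROM_DIRECTION = "assigned_from_direction"
    FLAGGED_UNKNOWN = "flagged_unknown"


class ScaleTag(str, enum.Enum):
    RAW_R = "raw_r"
    FISHER_Z = "fisher_z"


class DegenerateGroupsError(ValueError):
    """Raised when the pooled within-group variance is zero."""


class EmptyGroupError(ValueError):
    """Raised when one of the two groups has no observations."""


class IncompatibleTransformationError(ValueError):
    """Raised when a Fisher-z transform is requested for a mixed-origin dataset."""


@dataclass(frozen=True)
class GroupSummary:
    """Dark/light two-group summary: means, SDs and group sizes."""

    mean_dark: float
    mean_light: float
    sd_dark: float
    sd_light: float
    n_dark: int
    n_light: int

    def __post_init__(self) -> None:
        if self.sd_dark <= 0 or self.sd_light <= 0:
            raise ValueError("group SDs must be positive")
        if self.n_dark < 2 or self.n_light < 2:
            raise ValueError("each group needs at least 2 observations")

    @property
    def n_total(self) -> int:
        return self.n_dark + self.n_light


@dataclass(frozen=True)
class EffectSizeRecord:
    """One converted effect: correlation-scale value, variance, and sign provenance."""

    effect_id: str
    study_id: str
    species: str
    origin: Origin
    r: float
    v: float
    sign_source: SignSource
    scale_tag: ScaleTag = ScaleTag.RAW_R
    n_total: int | None = None
    n_dark: int | None = None
    n_light: int | None = None

    def __post_init__(self) -> None:
        if not (self.v > 0):
            raise ValueError(f"sampling variance must be positive, got {self.v}")
        if self.origin in UNSIGNED_ORIGINS and self.sign_source is SignSource.INHERENT:
            raise ValueError(f"{self.origin.value} effects cannot carry an inherent sign")
        if self.origin is not Origin.MEANS_SD_N and abs(self.r) > 1:
            raise ValueError("only biserial (means-SD-n) effects may exceed |r| = 1")


def standardized_difference(g: GroupSummary, variant: str = "fixed") -> float:
    """Standardized dark-light mean difference d.

    ``variant="fixed"`` divides the numerator by the pooled SD

        s_pooled = sqrt(((nL-1)·SD_L² + (nD-1)·SD_D²) / (nL+nD-2)),

    ``variant="buggy"`` reproduces the parentheses-missing denominator

        sqrt((nL-1)·SD_L² + (nD-1)·SD_D² / (nL+nD-2)),

    where the division applies to the dark-group summand only.  The buggy
    denominator is never smaller than the fixed one for nL+nD-2 > 1, so the
    buggy |d| is systematically attenuated.
    """
    if variant not in ("fixed", "buggy"):
        raise ValueError(f"unknown variant {variant!r}")
    num = g.mean_dark - g.mean_light
    ss_light = (g.n_light - 1) * g.sd_light**2
    ss_dark = (g.n_dark - 1) * g.sd_dark**2
    m = g.n_light + g.n_dark - 2
    if variant == "fixed":
        den_sq = (ss_light + ss_dark) / m
    else:
        den_sq = ss_light + ss_dark / m
    if den_sq <= 0:
        raise DegenerateGroupsError("degenerate groups: zero pooled variance")
    return num / math.sqrt(den_sq)


def _biserial_from_d(d: float, n_dark: int, n_light: int) -> tuple[float, float]:
    """d -> biserial r and its large-sample variance.

    Follows the reference meta-analytic implementation: d is mapped to the
    point-biserial with h = m·(1/n1 + 1/n2), m = n1 + n2 - 2, then ascended to
    the biserial with sqrt(p·q)/φ(Φ⁻¹(p)) using the observed group proportion
    p.  The variance is Soper's large-sample approximation for the biserial
    correlation.
    """
    n = n_dark + n_light
    p = n_dark / n
    q = 1.0 - p
    if p <= 0.0 or p >= 1.0:
        raise EmptyGroupError("one empty group")
    m = n - 2
    h = m / n_dark + m / n_light
    rpb = d / math.sqrt(d * d + h)
    u = norm.ppf(p)
    dens = norm.pdf(u)
    c = math.sqrt(p * q) / dens
    rb = c * rpb
    v = (
        p * q / dens**2
        - (1.5 + (1.0 - p * u / dens) * (1.0 + q * u / dens)) * rb**2
        + rb**4
    ) / (n - 1)
    return rb, v


def rbis_from_group_summary(g: GroupSummary, variant: str = "fixed") -> tuple[float, float]:
    """Biserial correlation (and sampling variance) from a two-group summary.

    The biserial treats the dark/light dichotomy as an artificial cut of a
    latent continuous trait; unlike the point-biserial it can exceed |1| in
    samples, and such values are propagated, not clipped.
    """
    if g.n_total < 4:
        raise ValueError("need at least 4 observations in total")
    d = standardized_difference(g, variant=variant)
    return _biserial_from_d(d, g.n_dark, g.n_light)


def r_from_t(t: float, df: int, n_total: int | None = None) -> tuple[float, float]:
    """Pearson correlation from a t statistic: r = t/sqrt(t² + df), sign kept."""
    if df < 1:
        raise ValueError("t-statistic df must be >= 1")
    r = t / math.sqrt(t * t + df)
    n = n_total if n_total is not None else df + 2
    return r, sampling_variance_r(r, n)


def cramers_v(chi2: float, n: int, rows: int = 2, cols: int = 2) -> tuple[float, float]:
    """Cramér's V from a chi-square statistic of an rows×cols contingency table.

    V = sqrt(χ² / (n·(min(rows, cols) - 1))) lies in [0, 1] and is inherently
    unsigned; a direction must be assigned afterwards via :func:`assign_sign`.
    The variance uses the correlation-scale large-sample convention.
    """
    if chi2 < 0:
        raise ValueError("chi-square statistic cannot be negative")
    if rows < 2 or cols < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    if n < 4:
        raise ValueError("need n >= 4")
    V = math.sqrt(chi2 / (n * (min(rows, cols) - 1)))
    V = min(V, 1.0)
    return V, sampling_variance_r(V, n)


def eta_squared_from_F(F: float, df1: int, df2: int, n_total: int | None = None
                       ) -> tuple[float, float, float]:
    """Eta-squared (and its correlation-scale magnitude) from an omnibus F.

    η² = F·df1/(F·df1 + df2); r_magnitude = sqrt(η²).  For df1 = 1 this equals
    the r obtained from t = sqrt(F) with df = df2.  Unsigned: direction must
    be assigned via :func:`assign_sign`.  Returns (η², r_magnitude, v) with v
    on the correlation scale.
    """
    if F < 0:
        raise ValueError("F statistic cannot be negative")
    if df1 < 1 or df2 < 1:
        raise ValueError("F dfs must be positive")
    eta2 = F * df1 / (F * df1 + df2)
    r_mag = math.sqrt(eta2)
    n = n_total if n_total is not None else df1 + df2 + 1
    return eta2, r_mag, sampling_variance_r(r_mag, n)


def sampling_variance_r(r: float, n: int) -> float:
    """Large-sample sampling variance of a correlation: (1 - r²)²/(n - 1).

    Biserial effects with |r| > 1 do not use this; their variance comes from
    :func:`rbis_from_group_summary`.
    """
    if n < 3:
        raise ValueError("insufficient sample size (n < 3)")
    v = (1.0 - r * r) ** 2 / (n - 1)
    if v <= 0:  # |r| exactly 1: floor at a tiny positive value
        v = 1.0 / (n - 1) ** 2
    return v


def assign_sign(magnitude: float, direction: Direction | str,
                scale_reversed: bool = False) -> tuple[float, SignSource]:
    """Assign a direction to an unsigned effect-size magnitude.

    Traits measured on reversed scales (e.g. latency, where larger values mean
    *less* aggression) flip the reported direction before signing.  Unknown
    directions keep the magnitude but are flagged; flagged records are
    excluded from model fits by default.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    direction = Direction(direction)
    if direction is Direction.UNKNOWN:
        return magnitude, SignSource.FLAGGED_UNKNOWN
    sign = 1.0 if direction is Direction.POSITIVE else -1.0
    if scale_reversed:
        sign = -sign
    return sign * magnitude, SignSource.ASSIGNED_FROM_DIRECTION


def fisher_z_guard(records: Sequence[EffectSizeRecord], requested_scale: ScaleTag | str
                   ) -> list[EffectSizeRecord]:
    """Validate (and apply) the requested effect-size scale.

    The Fisher z transform z = atanh(r), v_z = 1/(n-3) is only valid for
    genuine Pearson correlations.  Biserial, Cramér's-V and eta-squared
    derived effects require different stabilizing transforms, so requesting
    ``fisher_z`` on a dataset mixing those origins with Pearson r is a hard
    error rather than a silent approximation.
    """
    requested_scale = ScaleTag(requested_scale)
    records = list(records)
    if requested_scale is ScaleTag.RAW_R:
        return records
    origins = {rec.origin for rec in records}
    allowed = {Origin.PEARSON_R, Origin.T_VALUE}
    if not origins <= allowed:
        bad = sorted(o.value for o in origins - allowed)
        raise IncompatibleTransformationError(
            "incompatible transformation: Fisher z requested for a dataset with "
            f"non-Pearson origins {bad}; combine on the raw r scale instead"
        )
    out = []
    for rec in records:
        if abs(rec.r) >= 1:
            raise IncompatibleTransformationError(
                f"effect {rec.effect_id}: |r| >= 1 cannot be z-transformed"
            )
        n = rec.n_total if rec.n_total is not None else None
        if n is None or n < 4:
            raise IncompatibleTransformationError(
                f"effect {rec.effect_id}: Fisher z needs n_total >= 4"
            )
        out.append(replace(rec, r=math.atanh(rec.r), v=1.0 / (n - 3),
                           scale_tag=ScaleTag.FISHER_Z))
    return out


def sign_distribution_audit(records: Sequence[EffectSizeRecord],
                            margin: float = 25.0) -> pd.DataFrame:
    """Per-origin count and percent-positive table, with a gradient warning.

    A markedly higher share of positive effects among inherently unsigned
    origins (F, chi-square) than among signed ones (r, means-SD-n, t) is a
    signature of directions having been defaulted to positive at extraction.
    The ``warning`` column flags origins from unsigned statistics whose
    percent-positive exceeds the signed origins' average by more than
    ``margin`` percentage points.
    """
    rows = []
    by_origin: dict[Origin, list[EffectSizeRecord]] = {}
    for rec in records:
        by_origin.setdefault(rec.origin, []).append(rec)
    signed_pcts = [100.0 * np.mean([r.r > 0 for r in recs])
                   for o, recs in by_origin.items() if o not in UNSIGNED_ORIGINS]
    signed_ref = float(np.mean(signed_pcts)) if signed_pcts else math.nan
    for origin in Origin:
        recs = by_origin.get(origin)
        if not recs:
            continue
        pct = 100.0 * float(np.mean([r.r > 0 for r in recs]))
        warn = bool(
            origin in UNSIGNED_ORIGINS
            and not math.isnan(signed_ref)
            and pct - signed_ref > margin
        )
        rows.append({"origin": origin.value, "k": len(recs),
                     "percent_positive": round(pct, 1), "warning": warn})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV-level conversion
# ---------------------------------------------------------------------------

#: input columns of the effect-size extraction table
INPUT_COLUMNS = [
    "effect_id", "study_id", "species", "origin", "stat_value", "df1", "df2",
    "rows", "cols", "mean_dark", "sd_dark", "n_dark", "mean_light", "sd_light",
    "n_light", "n_total", "direction", "scale_reversed",
]


def _maybe_int(value) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return int(value)


def convert_row(row: pd.Series, variant: str = "fixed") -> EffectSizeRecord:
    """Convert one extraction-table row to an :class:`EffectSizeRecord`."""
    origin = Origin(row["origin"])
    reversed_ = bool(row.get("scale_reversed", False))
    direction = Direction(row["direction"]) if isinstance(row.get("direction"), str) \
        and row["direction"] else Direction.UNKNOWN
    n_total = _maybe_int(row.get("n_total"))
    n_dark = _maybe_int(row.get("n_dark"))
    n_light = _maybe_int(row.get("n_light"))

    if origin is Origin.PEARSON_R:
        r = float(row["stat_value"])
        if n_total is None:
            raise ValueError(f"effect {row['effect_id']}: Pearson r needs n_total")
        v = sampling_variance_r(r, n_total)
        sign_source = SignSource.INHERENT
    elif origin is Origin.MEANS_SD_N:
        g = GroupSummary(
            mean_dark=float(row["mean_dark"]), mean_light=float(row["mean_light"]),
            sd_dark=float(row["sd_dark"]), sd_light=float(row["sd_light"]),
            n_dark=int(row["n_dark"]), n_light=int(row["n_light"]),
        )
        r, v = rbis_from_group_summary(g, variant=variant)
        n_total = g.n_total
        sign_source = SignSource.INHERENT
    elif origin is Origin.T_VALUE:
        r, v = r_from_t(float(row["stat_value"]), int(row["df2"]), n_total)
        if n_total is None:
            n_total = int(row["df2"]) + 2
        sign_source = SignSource.INHERENT
    elif origin is Origin.F_VALUE:
        if n_total is None:
            n_total = int(row["df1"]) + int(row["df2"]) + 1
        _, r_mag, v = eta_squared_from_F(
            float(row["stat_value"]), int(row["df1"]), int(row["df2"]), n_total)
        r, sign_source = assign_sign(r_mag, direction, reversed_)
    else:  # chi-square
        if n_total is None:
            raise ValueError(f"effect {row['effect_id']}: chi-square needs n_total")
        V, v = cramers_v(float(row["stat_value"]), n_total,
                         int(row["rows"]), int(row["cols"]))
        r, sign_source = assign_sign(V, direction, reversed_)

    if sign_source is SignSource.INHERENT and reversed_:
        r = -r
    return EffectSizeRecord(
        effect_id=str(row["effect_id"]), study_id=str(row["study_id"]),
        species=str(row["species"]), origin=origin, r=r, v=v,
        sign_source=sign_source, n_total=n_total, n_dark=n_dark, n_light=n_light,
    )


def convert_table(df: pd.DataFrame, variant: str = "fixed") -> pd.DataFrame:
    """Convert an extraction table; appends ``r, v, sign_source, scale_tag``."""
    records = [convert_row(row, variant=variant) for _, row in df.iterrows()]
    out = df.copy()
    out["r"] = [rec.r for rec in records]
    out["v"] = [rec.v for rec in records]
    out["sign_source"] = [rec.sign_source.value for rec in records]
    out["scale_tag"] = [rec.scale_tag.value for rec in records]
    return out


def records_from_table(df: pd.DataFrame, variant: str = "fixed",
                       keep_unsigned: bool = False) -> list[EffectSizeRecord]:
    """Extraction table -> effect records, dropping unknown-direction effects.

    ``keep_unsigned=True`` retains unknown-direction effects at +magnitude
    (the legacy default-positive behaviour, for comparison runs only).
    """
    records = [convert_row(row, variant=variant) for _, row in df.iterrows()]
    if keep_unsigned:
        return records
    return [r for r in records if r.sign_source is not SignSource.FLAGGED_UNKNOWN]
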