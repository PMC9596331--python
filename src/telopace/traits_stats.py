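"""Trait table loading, lifespan decomposition, and non-phylogenetic statistics.

The central operation splits (log) maximum lifespan into two orthogonal
life-history components via ordinary least squares on (log) adult female
body mass: the fitted values ("mass-predicted lifespan", the body-size
component) and the residuals ("mass-independent lifespan", position on the
slow-fast pace-of-life continuum). Pearson correlations come with the full
frequentist inference (t, df, p, Fisher-z confidence interval) and Cohen
effect-size labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TraitTable",
    "LifespanDecomposition",
    "CorrelationResult",
    "load_traits",
    "decompose_lifespan",
    "pearson_with_inference",
    "normality_check",
    "effect_size_label",
    "DEFAULT_COLUMN_MAP",
]

#: file column -> trait role, for the standard CSV layout
DEFAULT_COLUMN_MAP = {
    "species": "species",
    "body_mass_g": "body_mass",
    "max_lifespan_y": "max_lifespan",
    "telomere_length_kb": "telomere_length",
    "troc_kb_per_y": "troc",
}

_ANALYSIS_COLUMNS = ["body_mass", "max_lifespan", "telomere_length", "troc"]


@dataclass
class TraitTable:
    """Validated per-species trait records.

    ``data`` has one row per species with columns ``species``, ``body_mass``
    (g), ``max_lifespan`` (years), ``telomere_length`` (kb), ``troc``
    (kb/year, negative = shortening), plus ``log_mass`` and ``log_lifespan``
    (base-10, always recomputed from the raw columns).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        dups = df["species"][df["species"].duplicated()].tolist()
        if dups:
            raise ValueError(f"duplicate species names: {sorted(set(dups))}")
        for col in _ANALYSIS_COLUMNS:
            if df[col].isna().any():
                raise ValueError(f"missing values in column {col!r}")
        if (df["body_mass"] <= 0).any() or (df["max_lifespan"] <= 0).any():
            raise ValueError("body_mass and max_lifespan must be positive")
        df["log_mass"] = np.log10(df["body_mass"].to_numpy(float))
        df["log_lifespan"] = np.log10(df["max_lifespan"].to_numpy(float))
        self.data = df

    @property
    def species(self) -> list[str]:
        return self.data["species"].tolist()

    @property
    def n_species(self) -> int:
        return len(self.data)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy(float)

    def subset(self, species: list[str]) -> "TraitTable":
        """Rows for ``species``, in that order."""
        df = self.data.set_index("species").loc[species].reset_index()
        return TraitTable(df)

    def to_csv(self, path) -> None:
        out = self.data[["species"] + _ANALYSIS_COLUMNS].rename(
            columns={v: k for k, v in DEFAULT_COLUMN_MAP.items()}
        )
        out.to_csv(path, index=False)


def load_traits(
    source,
    column_map: dict[str, str] | None = None,
    average_duplicates: bool = False,
) -> TraitTable:
    """Load a species trait CSV into a validated :class:`TraitTable`.

    ``column_map`` maps file columns to trait roles (default
    :data:`DEFAULT_COLUMN_MAP`). Rows with any missing analysis value are
    dropped with a logged count; ``average_duplicates=True`` averages the
    numeric columns of repeated species rows (multiple literature sources)
    instead of erroring.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    df = pd.read_csv(source)
    missing_cols = [c for c in column_map if c not in df.columns]
    if missing_cols:
        raise ValueError(f"CSV is missing mapped columns: {missing_cols}")
    df = df[list(column_map)].rename(columns=column_map)

    for col in _ANALYSIS_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    n_before = len(df)
    df = df.dropna(subset=_ANALYSIS_COLUMNS)
    if n_before - len(df):
        logger.warning(
            "dropped %d record(s) with missing analysis values", n_before - len(df)
        )
    if average_duplicates and df["species"].duplicated().any():
        df = df.groupby("species", as_index=False, sort=False).mean(numeric_only=True)
    if len(df) < 3:
        raise ValueError(f"only {len(df)} complete records; at least 3 required")
    return TraitTable(df)


@dataclass
class LifespanDecomposition:
    """OLS split of log lifespan into mass-predicted and mass-independent parts."""

    intercept: float
    slope: float
    r_squared: float
    f_stat: float
    df_num: int
    df_den: int
    species: list[str]
    mass_predicted: np.ndarray = field(repr=False)
    mass_independent: np.ndarray = field(repr=False)
    shapiro_w: float = math.nan
    shapiro_p: float = math.nan

    def to_frame(self, traits: TraitTable) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "log_mass": traits["log_mass"],
                "log_lifespan": traits["log_lifespan"],
                "mass_predicted": self.mass_predicted,
                "mass_independent": self.mass_independent,
            }
        )

    def summary_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "r_squared": self.r_squared,
            "f_stat": self.f_stat,
            "df": [self.df_num, self.df_den],
            "shapiro_w": self.shapiro_w,
            "shapiro_p": self.shapiro_p,
        }


def decompose_lifespan(traits: TraitTable) -> LifespanDecomposition:
    """Regress log10 lifespan on log10 mass and split into the two components.

    Returns coefficients, R², the regression F with (1, n-2) degrees of
    freedom, fitted values (mass-predicted lifespan), residuals
    (mass-independent lifespan), and the Shapiro-Wilk normality check of the
    residuals. Requires at least 3 species and non-constant log mass.
    """
    if traits.n_species < 3:
        raise ValueError("decompose_lifespan requires at least 3 species")
    x = traits["log_mass"]
    y = traits["log_lifespan"]
    if np.ptp(x) == 0:
        raise ValueError("log_mass is constant; allometric slope is undefined")

    fit = stats.linregress(x, y)
    predicted = fit.intercept + fit.slope * x
    residuals = y - predicted
    n = len(x)
    r2 = float(fit.rvalue**2)
    if r2 >= 1.0:
        f = math.inf
    else:
        f = r2 / (1 - r2) * (n - 2)
    if np.ptp(residuals) > 0:
        w, p = stats.shapiro(residuals)
    else:
        w, p = 1.0, 1.0
    return LifespanDecomposition(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=r2,
        f_stat=float(f),
        df_num=1,
        df_den=n - 2,
        species=traits.species,
        mass_predicted=predicted,
        mass_independent=residuals,
        shapiro_w=float(w),
        shapiro_p=float(p),
    )


@dataclass
class CorrelationResult:
    """Pearson correlation with t-test inference and effect-size label."""

    r: float
    t_stat: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float
    effect_label: str

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "t": self.t_stat,
            "df": self.df,
            "p": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "effect": self.effect_label,
        }


def effect_size_label(r: float) -> str:
    """Cohen's effect-size band for a correlation: |r| ≥ 0.5 is large,
    ≥ 0.3 medium, ≥ 0.1 small, below that trivial."""
    a = abs(r)
    if a > 1:
        raise ValueError(f"|r| = {a} exceeds 1")
    if a >= 0.5:
        return "large"
    if a >= 0.3:
        return "medium"
    if a >= 0.1:
        return "small"
    return "trivial"


def pearson_with_inference(x, y) -> CorrelationResult:
    """Pearson r with t statistic, df = n-2, two-sided p, and 95% Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: correlation undefined")

    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    df = n - 2
    if abs(r) < 1.0:
        t = r * math.sqrt(df) / math.sqrt(1 - r * r)
    else:
        t = math.copysign(math.inf, r)
    p = float(res.pvalue)
    # Fisher z interval; degenerate at |r| = 1
    if abs(r) < 1.0 and n > 3:
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
    else:
        lo = hi = r
    return CorrelationResult(
        r=r,
        t_stat=float(t),
        df=df,
        p_value=p,
        ci_low=float(lo),
        ci_high=float(hi),
        effect_label=effect_size_label(r),
    )


def normality_check(residuals) -> tuple[float, float, pd.DataFrame]:
    """Shapiro-Wilk test plus Q-Q plot coordinates for a residual vector.

    Returns ``(W, p, qq)`` where ``qq`` has columns ``theoretical`` (standard
    normal order-statistic medians) and ``sample`` (sorted residuals), ready
    for plotting or CSV export.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise ValueError("normality_check requires at least 3 values")
    if r.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable beyond n = 5000")
    w, p = stats.shapiro(r)
    osm, osr = stats.probplot(r, dist="norm", fit=False)
    qq = pd.DataFrame({"theoretical": osm, "sample": osr})
    return float(w), float(p), qq
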