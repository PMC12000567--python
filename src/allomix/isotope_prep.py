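"""Trophic levels and water-exchange (omega) corrections for consumer isotopes.

Consumer tissue hydrogen partly derives from environmental water rather than
diet; the per-trophic-level proportion omega compounds over the food chain as

    omega_compound = 1 - (1 - omega)^(TL - 1)

and the measured consumer delta-2H is corrected back onto the source scale with

    d2H_corrected = (d2H_consumer - omega_compound * d2H_water) / (1 - omega_compound).

Trophic level comes from a single-end-member nitrogen model
``TL = baseline_TL + (d15N_consumer - d15N_baseline) / TDF_N`` with herbivorous
baselines at TL 2.1; lakes lacking a measured baseline taxon are imputed from
a cross-lake regression on a surrogate group, and zoobenthos with a methane
carbon-isotope signal have their TL fixed at the baseline level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


class MissingBaselineError(KeyError):
    """No baseline delta-15N could be resolved for a lake/compartment."""


@dataclass
class TrophicConfig:
    """Constants of the trophic-level and omega-correction step.

    Parameters
    ----------
    baseline_tl : float
        Trophic level assigned to the herbivorous baseline taxa (default 2.1).
    baseline_tl_sd : float
        Its uncertainty (SD, default 0.1); propagated only through
        ``extra_consumer_sd``.
    tdf_n, tdf_n_sd : float
        Trophic discrimination factor for delta-15N in permil (3.4 +- 1.0).
    tdf_h : float
        Trophic discrimination factor for delta-2H (0 here).
    omega, omega_sd : float
        Per-trophic-level proportion of tissue H exchanged with water
        (0.23 +- 0.09).
    extra_consumer_sd : float
        Additional observation SD (permil) attached to every omega-corrected
        value, representing propagated baseline/TDF/omega uncertainty
        (default 13).
    methane_d13c_threshold : float
        delta-13C (permil) at or below which a zoobenthos sample is treated as
        methane-influenced and its TL fixed to ``baseline_tl`` (default -40).
    """

    baseline_tl: float = 2.1
    baseline_tl_sd: float = 0.1
    tdf_n: float = 3.4
    tdf_n_sd: float = 1.0
    tdf_h: float = 0.0
    omega: float = 0.23
    omega_sd: float = 0.09
    extra_consumer_sd: float = 13.0
    methane_d13c_threshold: float = -40.0

    def __post_init__(self):
        if not (0.0 <= self.omega < 1.0):
            raise ValueError(f"omega must be in [0, 1), got {self.omega}")
        if self.tdf_n == 0:
            raise ValueError("tdf_n must be nonzero")
        if self.extra_consumer_sd < 0:
            raise ValueError("extra_consumer_sd must be >= 0")


def estimate_trophic_level(d15n_consumer, d15n_baseline, cfg: TrophicConfig | None = None):
    """Trophic level from the single-end-member nitrogen model.

    ``TL = baseline_tl + (d15N_consumer - d15N_baseline) / tdf_n``; values
    below 1 (consumer apparently below the basal hydrogen source) are clamped
    to 1 with a warning.
    """
    cfg = cfg or TrophicConfig()
    tl = cfg.baseline_tl + (np.asarray(d15n_consumer, float) - np.asarray(d15n_baseline, float)) / cfg.tdf_n
    clamped = tl < 1.0
    if np.any(clamped):
        warnings.warn(
            f"{int(np.sum(clamped))} trophic level(s) below 1 clamped to 1", stacklevel=2
        )
        tl = np.where(clamped, 1.0, tl)
    return tl if np.ndim(tl) else float(tl)


def fit_baseline_regression(x, y):
    """OLS of baseline-group lake means on a surrogate group's lake means.

    Returns ``(slope, intercept, adjusted_r2)`` where
    ``adjusted R^2 = 1 - (1 - R^2) (n - 1) / (n - 2)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError(f"baseline regression needs >= 3 paired lakes, got {n}")
    if np.var(x) == 0:
        raise ValueError("predictor group delta-15N has zero variance")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(res.slope), float(res.intercept), float(adj_r2)


def impute_missing_baselines(baseline_values: dict, predictor_values: dict, regression) -> pd.DataFrame:
    """Resolve a per-lake baseline map, imputing missing lakes by regression.

    Parameters
    ----------
    baseline_values : dict
        ``{lake_id: measured baseline d15N or None}``.
    predictor_values : dict
        ``{lake_id: surrogate-group lake-mean d15N}`` used where the baseline
        is missing.
    regression : (slope, intercept) or the 3-tuple from
        :func:`fit_baseline_regression`.

    Returns
    -------
    DataFrame with columns ``lake_id``, ``d15n_baseline``, ``imputed``.
    """
    slope, intercept = regression[0], regression[1]
    rows = []
    for lake, measured in baseline_values.items():
        if measured is not None and np.isfinite(measured):
            rows.append((lake, float(measured), False))
            continue
        pred = predictor_values.get(lake)
        if pred is None or not np.isfinite(pred):
            raise MissingBaselineError(
                f"lake {lake!r}: no measured baseline and no predictor group to impute from"
            )
        rows.append((lake, float(slope * pred + intercept), True))
    return pd.DataFrame(rows, columns=["lake_id", "d15n_baseline", "imputed"])


def fix_methane_influenced(samples: pd.DataFrame, cfg: TrophicConfig | None = None) -> pd.DataFrame:
    """Fix TL of methane-influenced samples (very depleted delta-13C) to baseline.

    Operates on a frame with ``tl`` and optional ``d13c`` columns; returns a
    copy with ``tl`` overwritten and a boolean ``methane_fixed`` column.  If no
    delta-13C column is present the rule is skipped and logged.
    """
    cfg = cfg or TrophicConfig()
    out = samples.copy()
    if "d13c" not in out.columns or out["d13c"].isna().all():
        logger.info("no d13c values present; methane screening skipped")
        out["methane_fixed"] = False
        return out
    flag = out["d13c"].notna() & (out["d13c"] <= cfg.methane_d13c_threshold)
    out.loc[flag, "tl"] = cfg.baseline_tl
    out["methane_fixed"] = flag.to_numpy()
    if flag.any():
        logger.info("fixed TL of %d methane-influenced sample(s) to %.2f", int(flag.sum()), cfg.baseline_tl)
    return out


def omega_compound(omega, tl):
    """Compound water-hydrogen proportion ``1 - (1 - omega)^(TL - 1)``.

    Continuous in ``tl``; TL 1 (the basal source level) gives 0.
    """
    omega = np.asarray(omega, float)
    tl = np.asarray(tl, float)
    if np.any((omega < 0) | (omega >= 1)):
        raise ValueError("omega must be in [0, 1)")
    if np.any(tl < 1):
        raise ValueError("trophic level must be >= 1")
    oc = 1.0 - (1.0 - omega) ** (tl - 1.0)
    return oc if oc.ndim else float(oc)


def omega_correct(d2h_c, d2h_water, omega_compound):
    """Remove the environmental-water hydrogen share from a consumer value.

    ``(d2h_c - omega_compound * d2h_water) / (1 - omega_compound)``.
    """
    oc = np.asarray(omega_compound, float)
    if np.any((oc < 0) | (oc >= 1)):
        raise ValueError("omega_compound must be in [0, 1)")
    out = (np.asarray(d2h_c, float) - oc * np.asarray(d2h_water, float)) / (1.0 - oc)
    return out if out.ndim else float(out)


def corrected_sd(cfg: TrophicConfig | None = None) -> float:
    """Observation-level SD (permil) attached to every corrected value."""
    cfg = cfg or TrophicConfig()
    return float(cfg.extra_consumer_sd)


class ConsumerPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer turning raw consumer isotope rows into model-ready rows.

    ``fit`` resolves per-lake baselines (per food-web compartment) from the
    consumer table itself, fitting cross-lake imputation regressions where a
    lake lacks its baseline taxon; ``transform`` adds trophic level, the
    compound omega, the omega-corrected delta-2H and its SD, plus bookkeeping
    flags.

    Parameters
    ----------
    config : TrophicConfig
    baseline_taxa : dict
        Compartment label -> baseline taxon name.  Default: herbivorous
        cladocerans for every compartment except littoral zoobenthos, which
        uses littoral *Asellus*.
    surrogate_taxa : dict
        Baseline taxon -> surrogate (bulk) taxon used to impute the baseline
        in lakes where it was not measured.
    group_col, taxon_col, lake_col : str
        Column names in the consumer frame.

    Attributes
    ----------
    baseline_map_ : DataFrame
        lake_id x compartment baseline values with imputation flags.
    regressions_ : dict
        Baseline taxon -> (slope, intercept, adjusted R^2).
    """

    def __init__(
        self,
        config: TrophicConfig | None = None,
        baseline_taxa: dict | None = None,
        surrogate_taxa: dict | None = None,
        group_col: str = "group",
        taxon_col: str = "taxon",
        lake_col: str = "lake_id",
    ):
        self.config = config
        self.baseline_taxa = baseline_taxa
        self.surrogate_taxa = surrogate_taxa
        self.group_col = group_col
        self.taxon_col = taxon_col
        self.lake_col = lake_col

    # -- helpers -----------------------------------------------------------
    def _cfg(self) -> TrophicConfig:
        return self.config or TrophicConfig()

    def _baseline_taxa(self, groups) -> dict:
        if self.baseline_taxa is not None:
            return dict(self.baseline_taxa)
        return {g: ("asellus" if "littoral" in str(g).lower() else "cladocera") for g in groups}

    def _surrogates(self) -> dict:
        if self.surrogate_taxa is not None:
            return dict(self.surrogate_taxa)
        return {"cladocera": "bulk_zooplankton", "asellus": "bulk_zoobenthos_littoral"}

    def fit(self, X: pd.DataFrame, y=None):
        X = X.copy()
        groups = X[self.group_col].unique()
        bmap = self._baseline_taxa(groups)
        surrogates = self._surrogates()
        lakes = list(pd.unique(X[self.lake_col]))

        taxon_means = (
            X.groupby([self.lake_col, self.taxon_col])["d15n"].mean().unstack(self.taxon_col)
        )

        self.regressions_ = {}
        rows = []
        for baseline_taxon in sorted(set(bmap.values())):
            measured = (
                taxon_means[baseline_taxon]
                if baseline_taxon in taxon_means
                else pd.Series(np.nan, index=taxon_means.index)
            )
            missing = [lk for lk in lakes if lk not in measured.index or pd.isna(measured.get(lk))]
            regression = None
            if missing:
                surrogate = surrogates.get(baseline_taxon)
                if surrogate is None or surrogate not in taxon_means:
                    raise MissingBaselineError(
                        f"baseline taxon {baseline_taxon!r} missing in lakes {missing} "
                        f"and no surrogate group available to impute from"
                    )
                paired = taxon_means[[baseline_taxon, surrogate]].dropna()
                regression = fit_baseline_regression(paired[surrogate], paired[baseline_taxon])
                self.regressions_[baseline_taxon] = regression
            for lk in lakes:
                val = measured.get(lk) if lk in measured.index else np.nan
                if pd.notna(val):
                    rows.append((lk, baseline_taxon, float(val), False))
                else:
                    pred = taxon_means.at[lk, surrogate] if lk in taxon_means.index else np.nan
                    if pd.isna(pred):
                        raise MissingBaselineError(
                            f"lake {lk!r}: baseline taxon {baseline_taxon!r} and surrogate "
                            f"{surrogate!r} both unmeasured"
                        )
                    slope, intercept, _ = regression
                    rows.append((lk, baseline_taxon, float(slope * pred + intercept), True))
                    logger.info("imputed %s baseline for lake %s", baseline_taxon, lk)

        self.baseline_map_ = pd.DataFrame(
            rows, columns=["lake_id", "baseline_taxon", "d15n_baseline", "imputed"]
        )
        self.compartment_baseline_ = bmap
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "baseline_map_"):
            raise RuntimeError("ConsumerPreprocessor must be fitted before transform")
        cfg = self._cfg()
        out = X.copy()
        bmap = self.compartment_baseline_
        lookup = self.baseline_map_.set_index(["lake_id", "baseline_taxon"])

        base_vals = np.empty(len(out))
        imputed = np.zeros(len(out), bool)
        for i, (lk, grp) in enumerate(zip(out[self.lake_col], out[self.group_col])):
            taxon = bmap.get(grp)
            if taxon is None:
                raise MissingBaselineError(f"no baseline taxon configured for compartment {grp!r}")
            try:
                rec = lookup.loc[(lk, taxon)]
            except KeyError:
                raise MissingBaselineError(f"no baseline for lake {lk!r} / compartment {grp!r}") from None
            base_vals[i] = rec["d15n_baseline"]
            imputed[i] = bool(rec["imputed"])

        out["d15n_baseline"] = base_vals
        out["baseline_imputed"] = imputed
        tl_raw = cfg.baseline_tl + (out["d15n"].to_numpy() - base_vals) / cfg.tdf_n
        out["tl_clamped"] = tl_raw < 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["tl"] = estimate_trophic_level(out["d15n"].to_numpy(), base_vals, cfg)
        if out["tl_clamped"].any():
            logger.warning("clamped %d trophic level(s) to 1", int(out["tl_clamped"].sum()))

        out = fix_methane_influenced(out, cfg)
        out["omega_compound"] = omega_compound(cfg.omega, out["tl"].to_numpy())
        if "d2h_water" not in out.columns:
            raise KeyError("consumer frame must carry a per-lake 'd2h_water' column before correction")
        out["d2h_corrected"] = omega_correct(
            out["d2h"].to_numpy(), out["d2h_water"].to_numpy(), out["omega_compound"].to_numpy()
        )
        out["d2h_corrected_sd"] = corrected_sd(cfg)
        return out
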