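"""Per-lake terrestrial and aquatic delta-2H source distributions.

The terrestrial end member is inlet dissolved organic matter (t-DOM); the
aquatic end member is lake-water delta-2H shifted by the photosynthetic
discrimination (default -110 permil, the mean benthic algae - water offset).
Spatiotemporal SDs (11.2 permil terrestrial, 23.6 permil aquatic) are applied
to every lake.  Two sensitivity scenarios replace the end members: a bacterial
step that mixes inlet DOM with lake water, and measured benthic algae as the
aquatic source.  Screening against the source envelope is diagnostic only —
no samples are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

SCENARIOS = ("inlet_dom", "bacterial", "benthic_algae")


@dataclass
class SourceConfig:
    """Source-construction constants.

    photosynthetic_discrimination : permil shift from water to aquatic
        production (default -110).
    sd_terrestrial, sd_aquatic : spatiotemporal SDs in permil (11.2, 23.6).
    scenario : 'inlet_dom' (main), 'bacterial' or 'benthic_algae'.
    bacterial_omega : water share in the bacterial-step terrestrial source
        (default 0.17).
    """

    photosynthetic_discrimination: float = -110.0
    sd_terrestrial: float = 11.2
    sd_aquatic: float = 23.6
    scenario: str = "inlet_dom"
    bacterial_omega: float = 0.17

    def __post_init__(self):
        if self.sd_terrestrial < 0 or self.sd_aquatic < 0:
            raise ValueError("source SDs must be >= 0")
        if not (0.0 <= self.bacterial_omega <= 1.0):
            raise ValueError("bacterial_omega must be in [0, 1]")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")


def aquatic_source(d2h_water, cfg: SourceConfig | None = None):
    """Photosynthesis-adjusted aquatic source: ``(water + discrimination, sd_aquatic)``."""
    cfg = cfg or SourceConfig()
    if d2h_water is None or not np.isfinite(d2h_water):
        raise ValueError("missing lake-water delta-2H value")
    return float(d2h_water) + cfg.photosynthetic_discrimination, cfg.sd_aquatic


def terrestrial_source(d2h_inlet_dom, cfg: SourceConfig | None = None, substitute=None):
    """Terrestrial source from inlet DOM: ``(inlet value, sd_terrestrial)``.

    If the lake has no measurable inlet, a substitute lake's value may be
    passed; the caller is expected to flag the substitution.
    """
    cfg = cfg or SourceConfig()
    val = d2h_inlet_dom
    if val is None or not np.isfinite(val):
        val = substitute
    if val is None or not np.isfinite(val):
        raise ValueError("no inlet-DOM delta-2H value and no substitute lake value")
    return float(val), cfg.sd_terrestrial


def bacterial_scenario_source(d2h_inlet_dom, d2h_water, cfg: SourceConfig | None = None):
    """Bacterial-step terrestrial source: ``inlet*(1-omega) + water*omega``.

    A convex combination, so the mean always lies between the inlet-DOM and
    lake-water values.
    """
    cfg = cfg or SourceConfig()
    for name, v in (("inlet DOM", d2h_inlet_dom), ("lake water", d2h_water)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"bacterial scenario requires a {name} delta-2H value")
    w = cfg.bacterial_omega
    return float(d2h_inlet_dom) * (1.0 - w) + float(d2h_water) * w, cfg.sd_terrestrial


class SourceBuilder(BaseEstimator, TransformerMixin):
    """Transformer mapping a per-lake source table to per-lake SourcePairs.

    Input columns: ``lake_id``, ``d2h_water``, ``d2h_inlet_dom`` (blanks
    allowed), optional ``d2h_benthic_algae`` and ``substitute_lake_id``.
    Output columns: ``lake_id``, ``terrestrial_mean``, ``terrestrial_sd``,
    ``aquatic_mean``, ``aquatic_sd``, ``scenario``, ``inlet_substituted``.
    """

    def __init__(self, config: SourceConfig | None = None):
        self.config = config

    def fit(self, X: pd.DataFrame, y=None):
        self.n_lakes_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cfg = self.config or SourceConfig()
        by_lake = X.set_index("lake_id")
        rows = []
        for lake, rec in by_lake.iterrows():
            water = rec.get("d2h_water")
            inlet = rec.get("d2h_inlet_dom")
            substituted = False
            if inlet is None or pd.isna(inlet):
                sub_lake = rec.get("substitute_lake_id")
                if sub_lake is None or (isinstance(sub_lake, float) and pd.isna(sub_lake)) or sub_lake == "":
                    raise ValueError(f"lake {lake!r}: no inlet-DOM value and no substitute lake")
                if sub_lake not in by_lake.index:
                    raise ValueError(f"lake {lake!r}: substitute lake {sub_lake!r} not in source table")
                inlet = by_lake.at[sub_lake, "d2h_inlet_dom"]
                if pd.isna(inlet):
                    raise ValueError(f"lake {lake!r}: substitute lake {sub_lake!r} also lacks inlet DOM")
                substituted = True

            if cfg.scenario == "bacterial":
                t_mean, t_sd = bacterial_scenario_source(inlet, water, cfg)
            else:
                t_mean, t_sd = terrestrial_source(inlet, cfg)

            if cfg.scenario == "benthic_algae":
                algae = rec.get("d2h_benthic_algae")
                if algae is None or pd.isna(algae):
                    raise ValueError(f"lake {lake!r}: benthic-algae scenario needs d2h_benthic_algae")
                a_mean, a_sd = float(algae), cfg.sd_aquatic
            else:
                a_mean, a_sd = aquatic_source(water, cfg)

            rows.append((lake, t_mean, t_sd, a_mean, a_sd, cfg.scenario, substituted))
        return pd.DataFrame(
            rows,
            columns=[
                "lake_id",
                "terrestrial_mean",
                "terrestrial_sd",
                "aquatic_mean",
                "aquatic_sd",
                "scenario",
                "inlet_substituted",
            ],
        )


def screen_consumers(prepared: pd.DataFrame, source_pairs: pd.DataFrame, k: float = 2.0) -> dict:
    """Count corrected consumer values outside the per-lake source envelope.

    The envelope runs from the lower end member minus ``k`` times *that*
    source's SD to the upper end member plus ``k`` times *its* SD.  Diagnostic
    only: nothing is removed.

    Returns a dict with ``k``, total/outside counts, per-compartment outside
    counts and a boolean ``outside`` Series aligned to ``prepared``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    sp = source_pairs.set_index("lake_id")
    lo = np.empty(len(prepared))
    hi = np.empty(len(prepared))
    for i, lake in enumerate(prepared["lake_id"]):
        rec = sp.loc[lake]
        ends = [(rec["terrestrial_mean"], rec["terrestrial_sd"]), (rec["aquatic_mean"], rec["aquatic_sd"])]
        ends.sort(key=lambda e: e[0])
        lo[i] = ends[0][0] - k * ends[0][1]
        hi[i] = ends[1][0] + k * ends[1][1]
    vals = prepared["d2h_corrected"].to_numpy()
    outside = (vals < lo) | (vals > hi)
    per_group = (
        pd.Series(outside, index=prepared.index).groupby(prepared["group"]).sum().astype(int).to_dict()
        if "group" in prepared.columns
        else {}
    )
    return {
        "k": float(k),
        "n_total": int(len(prepared)),
        "n_outside": int(outside.sum()),
        "outside_by_group": per_group,
        "outside": pd.Series(outside, index=prepared.index, name="outside"),
    }
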