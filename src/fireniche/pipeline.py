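"""End-to-end pipeline: weather -> indices -> datasets -> search -> reports.

This module glues the stages together behind one function per stage plus
:func:`run_pipeline`, which executes indices, dataset assembly, best-model
search, evaluation and pairwise comparison for every configured regime and
writes plain CSV/JSON/Markdown reports. All randomness (the synthetic
generator only; fitting is deterministic) flows from a single root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fire_indices, regimes, selection_eval, synthetic, weather_io
from .selection_eval import METEO_VARIABLES, MIXED_EXCLUDED_METEO

logger = logging.getLogger(__name__)

__all__ = ["daily_variable_table", "default_pools", "run_pipeline", "RunConfig"]

#: index columns exposed as model variables
INDEX_VARIABLES = list(fire_indices.INDEX_COLUMNS)


def daily_variable_table(
    series: weather_io.WeatherSeries,
    rain_day_threshold: float = 0.2,
    start_codes=fire_indices.DEFAULT_START_CODES,
) -> pd.DataFrame:
    """One row per day: weather, derived variables and all fire indices.

    The ``burn_in`` column flags leading days whose trailing windows or
    index spin-up are incomplete; downstream dataset assembly drops them.
    """
    derived = weather_io.derive_variables(series, rain_day_threshold=rain_day_threshold)
    indices = fire_indices.compute_indices(
        series, derived=derived, start_codes=start_codes, rain_day_threshold=rain_day_threshold
    )
    burn = derived["burn_in"].astype(bool) | indices["burn_in"].astype(bool)
    out = pd.concat(
        [
            series.frame.drop(columns=["gap_filled"], errors="ignore"),
            derived.drop(columns=["burn_in"]),
            indices.drop(columns=["burn_in"]),
        ],
        axis=1,
    )
    out["burn_in"] = burn
    return out


def default_pools(available: Sequence[str] | None = None) -> dict[str, list[str]]:
    """The three canonical variable pools: meteo, indices, mixed.

    The mixed pool combines the meteo variables (minus VPD, LastRainSum
    and DaysSinceRain) with all fire indices. If ``available`` is given,
    pools are restricted to those columns.
    """
    meteo = list(METEO_VARIABLES)
    idx = list(INDEX_VARIABLES)
    mixed = [v for v in meteo if v not in MIXED_EXCLUDED_METEO] + idx
    pools = {"meteo": meteo, "indices": idx, "mixed": mixed}
    if available is not None:
        avail = set(available)
        pools = {k: [v for v in vs if v in avail] for k, vs in pools.items()}
    return pools


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    weather_csv: str | Path | None = None
    fires_csv: str | Path | None = None
    site: Mapping | weather_io.SiteParams | None = None
    out_dir: str | Path = "fireniche_out"
    regimes: Mapping[str, regimes.RegimeSpec] | None = None
    pools: Mapping[str, Sequence[str]] | None = None
    families: Sequence[str] = ("maxent", "logistic")
    block_years: int = 2
    rho_max: float = 0.9
    rain_day_threshold: float = 0.2
    subset_sizes: tuple[int, int] = (2, 10)
    max_subsets_per_pool: int | None = 2000
    seed: int = 0
    # synthetic fallback when no weather CSV is given
    synth_weather: synthetic.WeatherGenConfig | None = None
    synth_ignition: Mapping[str, synthetic.IgnitionGenConfig] | None = None

    def config_hash(self) -> str:
        """Hash of the scientific settings (paths excluded)."""
        d = dataclasses.asdict(self)
        for key in ("out_dir", "weather_csv", "fires_csv"):
            d.pop(key, None)
        payload = json.dumps({k: str(v) for k, v in d.items()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns a dict with the per-regime dataset summaries, search results
    and comparison matrices. Reports written: ``regimes.csv`` (fire-day /
    background / prevalence per regime), per-regime ``search_<r>.csv``
    ranking, ``best_models_<r>.json``, ``comparisons_<r>.json``,
    ``roc_<r>_<pool>.csv`` curves, and ``run_log.json`` with the seed and
    config hash.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.regimes is not None:
        specs = dict(config.regimes)
    elif config.weather_csv is None:
        # synthetic fallback: clamp the default regimes to the generated span
        wcfg = config.synth_weather or synthetic.WeatherGenConfig()
        span = (wcfg.start_year, wcfg.start_year + wcfg.years - 1)
        specs = {
            name: dataclasses.replace(spec, period=span)
            for name, spec in regimes.default_regimes().items()
        }
    else:
        specs = dict(regimes.default_regimes())

    # --- stage: inputs
    if config.weather_csv is not None:
        series = weather_io.read_weather(config.weather_csv, site=config.site)
        events = weather_io.read_fires(config.fires_csv)
    else:
        wcfg = config.synth_weather or synthetic.WeatherGenConfig()
        series = synthetic.generate_weather(wcfg, seed=config.seed)
        events_parts = []
        table_tmp = daily_variable_table(series, config.rain_day_threshold)
        for name, spec in specs.items():
            icfg = (config.synth_ignition or {}).get(
                name,
                synthetic.IgnitionGenConfig(regime=spec, coefficients={"vpd": 1.0}, target_prevalence=0.08),
            )
            name_tag = int(hashlib.sha256(name.encode()).hexdigest()[:6], 16) % 1000
            events_parts.append(
                synthetic.generate_fires(
                    table_tmp[~table_tmp["burn_in"]], icfg, seed=config.seed + 1000 + name_tag
                )
            )
        events = pd.concat(events_parts, ignore_index=True)

    # --- stage: indices
    table = daily_variable_table(series, config.rain_day_threshold)
    table.to_csv(out_dir / "daily_variables.csv")

    pools = dict(config.pools or default_pools(table.columns))
    summaries, all_results = {}, {}
    regime_rows = []
    for name, spec in specs.items():
        ds = regimes.build_dataset(table, events, spec)
        regime_rows.append(ds.summary())
        folds = selection_eval.year_block_folds(spec.period, config.block_years)

        search = selection_eval.best_model_search(
            ds,
            pools,
            families=config.families,
            folds=folds,
            rho_max=config.rho_max,
            size_range=config.subset_sizes,
            max_subsets_per_pool=config.max_subsets_per_pool,
        )
        ranking = pd.DataFrame([r.summary() for r in search["results"]])
        ranking.to_csv(out_dir / f"search_{name}.csv", index=False)

        best = {f"{pool}/{family}": r.summary() for (pool, family), r in search["best"].items()}
        (out_dir / f"best_models_{name}.json").write_text(json.dumps(best, indent=1, sort_keys=True))

        # pairwise comparison of the per-(pool, family) best models
        comparisons = []
        keys = sorted(search["best"])
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                comparisons.append(selection_eval.compare(search["best"][ka], search["best"][kb]))
        (out_dir / f"comparisons_{name}.json").write_text(json.dumps(comparisons, indent=1))

        # ROC curves of the best model per pool (maxent if present)
        for (pool, family), res in search["best"].items():
            if family != config.families[0]:
                continue
            model = res.spec.fit(ds.frame)
            scores = res.spec.score(model, ds.frame)
            curve = selection_eval.roc_bg(scores[ds.labels], scores)
            curve.to_csv(out_dir / f"roc_{name}_{pool}.csv", index=False)

        summaries[name] = ds.summary()
        all_results[name] = search

    pd.DataFrame(regime_rows).to_csv(out_dir / "regimes.csv", index=False)
    (out_dir / "run_log.json").write_text(
        json.dumps(
            {
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "regimes": {k: summaries[k] for k in sorted(summaries)},
            },
            indent=1,
            sort_keys=True,
        )
    )
    return {"summaries": summaries, "search": all_results, "out_dir": out_dir}
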