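"""End-to-end report pipeline: simulate -> indicators -> score -> fit -> attribute.

Deterministic given the single configuration seed: all stage seeds are
derived from it, and outputs are written with a fixed float format so a
rerun with the same config is byte-identical (the manifest records the
SHA-256 of each artifact).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import counterfactual as cf
from . import io as fio
from . import regression as reg
from . import scoring
from . import synthetic as syn
from .config import PipelineConfig

log = logging.getLogger(__name__)

GROUP_LABELS = ("group_1", "group_2", "group_3", "group_4")

_FITTERS = {
    "tvc": reg.fit_tvc,
    "constant": reg.fit_fe_constant,
    "binned-tvc": reg.fit_binned_tvc,
    "binned-constant": reg.fit_binned_constant,
}


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Derive independent per-stage integer seeds from the config seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def default_group_map(regions, n_groups: int = 4) -> pd.DataFrame:
    labels = [f"group_{i + 1}" for i in range(n_groups)]
    return pd.DataFrame(
        {"region_id": list(regions), "group": [labels[i % n_groups] for i in range(len(regions))]}
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic-report pipeline; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_climate, s_shdi, s_panel, s_survey = stage_seeds(config.seed)

    log.info("stage 1/5: simulating climate (%d regions)", config.climate.n_regions)
    climate = syn.simulate_climate(dataclasses.replace(config.climate, seed=s_climate))
    regions = sorted(climate["region_id"].unique())

    gen = dataclasses.replace(config.panel, seed=s_panel)
    shdi = syn.simulate_shdi(regions, gen.study_years, seed=s_shdi)

    log.info("stage 2/5: climate indicators and panel generation")
    baseline = config.indicators.baseline
    panel = syn.simulate_panel(climate, gen, shdi, baseline=baseline)

    log.info("stage 3/5: survey microdata and scoring")
    responses = syn.simulate_fies_responses(
        panel,
        item_thresholds=config.survey.item_thresholds,
        respondents_per_region=config.survey.respondents_per_region,
        seed=s_survey,
    )
    prev = scoring.weighted_prevalence(responses, dialect=config.survey.dialect)
    panel_obs = panel.merge(prev, on=["region_id", "year"], validate="1:1")

    log.info("stage 4/5: fitting %s regressions", config.regression.spec)
    fitter = _FITTERS[config.regression.spec]
    fits = {
        outcome: fitter(panel_obs, outcome, cov=config.regression.cov)
        for outcome in ("msfi", "sfi")
    }

    log.info("stage 5/5: counterfactual attribution")
    scenarios = cf.counterfactual_anomaly(climate, baseline, gen.study_years)
    group_map = default_group_map(regions, config.attribution.n_groups)
    weights = None
    if config.attribution.weights.startswith("pop:"):
        weights = pd.read_csv(config.attribution.weights[4:])
    anomaly_fits = fits
    if config.regression.spec.startswith("binned"):
        # attribution needs anomaly slopes; fall back to the headline spec
        anomaly_fits = {
            outcome: reg.fit_tvc(panel_obs, outcome, cov=config.regression.cov)
            for outcome in ("msfi", "sfi")
        }
    attribution = cf.attribute(anomaly_fits, panel_obs, scenarios, group_map, weights)

    fio.write_climate(climate, out / "climate.csv")
    fio.write_responses(responses, out / "responses.csv")
    fio.write_panel(panel_obs, out / "panel.csv")
    fio.write_table(scenarios, out / "scenarios.csv")
    fio.write_table(group_map, out / "group_map.csv")
    for outcome, fit in fits.items():
        fio.write_table(fit.tidy(), out / f"coefficients_{outcome}.csv")
        fit.to_json(out / f"fit_{outcome}.json")
    fio.write_table(attribution, out / "attribution.csv")
    fio.write_table(cf.attribution_long(attribution), out / "attribution_long.csv")

    artifacts = sorted(p.name for p in out.iterdir() if p.suffix in (".csv", ".json") and p.name != "manifest.json")
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_seeds": [s_climate, s_shdi, s_panel, s_survey],
        "rows": {
            "climate": len(climate),
            "responses": len(responses),
            "panel": len(panel_obs),
            "respondents_dropped": prev.attrs.get("n_dropped", 0),
            "panel_rows_dropped": max(f.n_dropped for f in fits.values()),
        },
        "outputs": {name: _sha256(out / name) for name in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
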