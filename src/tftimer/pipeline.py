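"""End-to-end seeded scenario runner: generate -> quantify -> calibrate -> infer.

``run_scenario`` ties the stages into one reproducible pipeline.  A single
global seed fans out to fixed per-stage child seeds, so each stage can be
rerun independently with identical results.  All outputs (images, tidy
CSVs, a JSON summary, the echoed config and a log) land in the output
directory; the summary carries every statistic the downstream analysis
reports: regional membrane ratios and residence estimates (both inversion
methods), the Hh compartment partition, apical Hh-Rab7 overlaps, fitted
maturation half-times, and per-region/section channel means.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import fit_maturation, infer_residence_map
from .io import (
    child_seed,
    config_hash,
    write_config,
    write_image,
    write_table,
)
from .quantify import (
    compartment_partition,
    intensity_overlap,
    membrane_mask_from_channel,
    membrane_ratio,
    plot_profile,
    subtract_background,
)
from .synthetic import (
    PRESETS,
    ScenarioConfig,
    generate_disc_image,
    generate_pulse_series,
    scenario_preset,
)

__all__ = ["RunConfig", "PipelineError", "run_scenario", "quantify_disc"]

log = logging.getLogger("tftimer")


class PipelineError(RuntimeError):
    """A stage failure, named after the failing stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    scenario: str | ScenarioConfig = "wild_type"
    seed: int = 0
    out_dir: str | Path = "tftimer_run"
    sections: tuple = ("apical", "basolateral")
    inference_method: str = "curve_lookup"
    fit_calibration: bool = True
    pulse_noise_cv: float = 0.05
    pulse_replicates: int = 3
    write_images: bool = True

    def resolve_scenario(self) -> ScenarioConfig:
        if isinstance(self.scenario, ScenarioConfig):
            sc = self.scenario
        elif self.scenario in PRESETS:
            sc = scenario_preset(self.scenario, seed=child_seed(self.seed, "generate"))
        else:
            from .io import read_config

            sc = read_config(self.scenario)
        return dataclasses.replace(sc, seed=child_seed(self.seed, "generate"))


def quantify_disc(image, truth=None, region_masks=None, ap_masks=None, seed: int = 0):
    """Measurement stage: ratios, partition, overlaps, profiles, means.

    Region masks come from ground truth when available, otherwise must be
    supplied (external data entry point).
    """
    if truth is not None:
        region_masks = truth.region_masks
        ap_masks = truth.ap_masks
    if region_masks is None or ap_masks is None:
        raise PipelineError("quantify: region masks are required without ground truth")

    membrane = membrane_mask_from_channel(image.channel("basolateral", "membrane"))
    ratios = membrane_ratio(
        image.channel("basolateral", "slow"),
        image.channel("basolateral", "fast"),
        membrane, region_masks, seed=child_seed(seed, "ratio-bootstrap"),
    )
    hh_ap = subtract_background(image.channel("apical", "hh"))
    partition = compartment_partition(hh_ap, ap_masks)
    overlaps = {
        comp: intensity_overlap(
            image.channel("apical", "hh"),
            image.channel("apical", "rab7"),
            ap_masks[comp],
            image.pixel_size,
            seed=child_seed(seed, f"coloc-{comp}"),
            region=comp,
            channel_pair=("hh", "rab7"),
        )
        for comp in ("A", "P")
    }
    profiles = {
        (section, ch): plot_profile(
            image.channel(section, ch), image.pixel_size, region_masks=region_masks
        )
        for section in image.sections
        for ch in ("fast", "slow", "hh")
    }
    means = {
        (section, ch, label): float(image.channel(section, ch)[m].mean())
        for section in image.sections
        for ch in ("fast", "slow")
        for label, m in region_masks.items()
    }
    return dict(
        membrane_ratios=ratios, partition=partition, overlaps=overlaps,
        profiles=profiles, region_channel_means=means, membrane_mask=membrane,
    )


def run_scenario(config: RunConfig) -> dict:
    """Run the full pipeline; returns the result bundle (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    t0 = time.time()
    try:
        scenario = config.resolve_scenario()
        log.info(
            "run_scenario start: scenario=%s seed=%d version=%s config_hash=%s",
            scenario.name, config.seed, __version__, config_hash(scenario),
        )
        write_config(scenario, out / "config.yaml")

        stage = "generate"
        try:
            image, truth = generate_disc_image(scenario)
            if config.write_images:
                write_image(image, out / "images")
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err

        stage = "quantify"
        try:
            q = quantify_disc(image, truth, seed=config.seed)
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err

        stage = "calibrate"
        try:
            if config.fit_calibration:
                series = generate_pulse_series(
                    scenario.fluorophores,
                    noise_cv=config.pulse_noise_cv,
                    n_replicates=config.pulse_replicates,
                    seed=child_seed(config.seed, "pulse"),
                )
                write_table(series.to_frame(), out / "pulse_series.csv")
                fit = fit_maturation(
                    series, seed=child_seed(config.seed, "fit-bootstrap")
                )
                curve = fit.curve()
            else:
                from .kinetics import pulse_ratio_curve

                fit = None
                curve = pulse_ratio_curve(scenario.fluorophores)
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err

        stage = "infer"
        try:
            estimates = {
                method: infer_residence_map(
                    q["membrane_ratios"], curve,
                    pair=scenario.fluorophores, method=method,
                )
                for method in ("curve_lookup", "steady_state")
            }
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err

        # ---- result tables + JSON summary
        rows = []
        for label, rr in q["membrane_ratios"].items():
            rows.append(
                dict(region=label, metric="membrane_ratio", estimate=rr.ratio,
                     ci_lo=rr.ci_lo, ci_hi=rr.ci_hi, n=rr.n_pixels,
                     status=rr.status)
            )
        for method, est in estimates.items():
            for label, e in est.items():
                rows.append(
                    dict(region=label, metric=f"residence_h_{method}",
                         estimate=e.hours, ci_lo=e.ci_lo, ci_hi=e.ci_hi,
                         n=np.nan, status=e.status)
                )
        for comp, frac in q["partition"].items():
            rows.append(
                dict(region=comp, metric="hh_partition", estimate=frac,
                     ci_lo=np.nan, ci_hi=np.nan, n=np.nan, status="ok")
            )
        for comp, cr in q["overlaps"].items():
            rows.append(
                dict(region=comp, metric="hh_rab7_overlap", estimate=cr.fraction,
                     ci_lo=cr.ci_lo, ci_hi=cr.ci_hi, n=cr.n_puncta, status="ok")
            )
        metrics = pd.DataFrame(rows)
        write_table(metrics, out / "metrics.csv")
        write_table(truth.puncta, out / "ground_truth_puncta.csv")

        summary = dict(
            scenario=scenario.name,
            seed=int(config.seed),
            version=__version__,
            config_hash=config_hash(scenario),
            inference_method=config.inference_method,
            membrane_ratios={
                k: dict(ratio=_f(v.ratio), ci=[_f(v.ci_lo), _f(v.ci_hi)],
                        status=v.status)
                for k, v in q["membrane_ratios"].items()
            },
            residence_h={
                method: {
                    k: dict(hours=_f(e.hours), ci=[_f(e.ci_lo), _f(e.ci_hi)],
                            status=e.status)
                    for k, e in est.items()
                }
                for method, est in estimates.items()
            },
            hh_partition={k: _f(v) for k, v in q["partition"].items()},
            hh_rab7_overlap={
                k: dict(fraction=_f(v.fraction), ci=[_f(v.ci_lo), _f(v.ci_hi)],
                        n_puncta=int(v.n_puncta))
                for k, v in q["overlaps"].items()
            },
            region_channel_means={
                f"{sec}/{ch}/{label}": _f(v)
                for (sec, ch, label), v in q["region_channel_means"].items()
            },
            calibration=None if fit is None else dict(
                half_fast_h=_f(fit.half_fast), half_slow_h=_f(fit.half_slow),
                amplitude=_f(fit.amplitude),
                ci_half_fast_h=[_f(np.log(2) / fit.ci_m_fast[1]),
                                _f(np.log(2) / fit.ci_m_fast[0])],
                ci_half_slow_h=[_f(np.log(2) / fit.ci_m_slow[1]),
                                _f(np.log(2) / fit.ci_m_slow[0])],
            ),
            truth=dict(
                residence_times_h={k: _f(v) for k, v in truth.residence_times.items()},
                partition_realized=_f(truth.partition_realized),
                overlap_realized={k: _f(v) for k, v in truth.overlap_realized.items()},
            ),
        )
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("run_scenario done in %.1f s", time.time() - t0)
        return dict(
            image=image, truth=truth, quantification=q, calibration=fit,
            estimates=estimates, metrics=metrics, summary=summary, out_dir=out,
        )
    finally:
        log.removeHandler(handler)
        handler.close()


def _f(x):
    x = float(x)
    return None if not np.isfinite(x) else round(x, 6)
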