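"""Study orchestration: phantom -> IDIF -> fits -> maps -> contrast -> stats.

`run_study` executes the full quantification chain on one synthetic study
and writes CSV tables and NIfTI maps into a run directory, together with
the resolved configuration, so every run is reproducible from its output
directory alone.  `run_test_retest` repeats the chain on a paired study
and reduces the lesion tables to repeatability statistics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    ConfigurationError,
    IRREVERSIBLE_2TC,
    ModelSpec,
    ONE_TISSUE,
    REVERSIBLE_2TC,
)
from .fitting import akaike_select
from .parametric import (
    default_theta_grid,
    extract_voi_values,
    fit_parametric,
    patlak_voxelwise,
)
from .patlak import patlak_fit
from .quantify import calibrate_cutoff, extract_idif, tn_ratio
from .repeatability import bland_altman, deming_fit, repeatability_coefficient
from .synth import (
    AORTA_LABEL,
    LIVER_LABEL,
    PhantomSpec,
    PhantomStudy,
    make_phantom,
    make_test_retest,
)

__all__ = ["RunConfig", "run_study", "run_test_retest"]

log = logging.getLogger("petkin")

_MODEL_IDS = {"1TC": ONE_TISSUE, "2TC-3k": IRREVERSIBLE_2TC, "2TC-4k": REVERSIBLE_2TC}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    noise_scale: float = 0.6
    t_star: float = 15.0
    theta_min: float = 0.006
    theta_max: float = 3.0
    n_theta: int = 64
    weighting: str = "duration"
    rc_convention: str = "relative"
    suv_ref: float = 6.0
    models: tuple[str, ...] = ("1TC", "2TC-3k", "2TC-4k")
    vb_correction: bool = False
    wcv_pct: float = 10.8
    static_time_min: float = 120.0

    def __post_init__(self) -> None:
        if self.t_star < 0:
            raise ConfigurationError("t_star must be non-negative")
        if not (0 < self.theta_min < self.theta_max):
            raise ConfigurationError("need 0 < theta_min < theta_max")
        if self.n_theta < 2:
            raise ConfigurationError("n_theta must be at least 2")
        if self.weighting not in ("duration", "uniform"):
            raise ConfigurationError("weighting must be 'duration' or 'uniform'")
        if self.rc_convention not in ("relative", "log", "cv277"):
            raise ConfigurationError(f"unknown rc_convention {self.rc_convention!r}")
        unknown = set(self.models) - set(_MODEL_IDS)
        if unknown:
            raise ConfigurationError(f"unknown model ids {sorted(unknown)}")
        if self.noise_scale < 0 or self.wcv_pct < 0:
            raise ConfigurationError("noise_scale and wcv_pct must be non-negative")

    @property
    def model_specs(self) -> list[ModelSpec]:
        return [_MODEL_IDS[m] for m in self.models]

    def theta_grid(self) -> np.ndarray:
        return default_theta_grid(self.n_theta, self.theta_min, self.theta_max)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["models"] = list(d["models"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def _fit_weights(config: RunConfig, schedule) -> np.ndarray | None:
    if config.weighting == "duration":
        return None  # TAC default
    return np.ones(schedule.n_frames)


def run_study(
    config: RunConfig,
    outdir,
    study: PhantomStudy | None = None,
) -> dict:
    """Run the full quantification chain and write its result bundle.

    Outputs (all under ``outdir``): ``config.yaml``, ``voi_fits.csv`` (one
    row per VOI x model, NLLS), ``patlak_voi.csv``, parametric maps as
    NIfTI (K1, Ki2TC, Vb, VND, KiPatlak, Ve), ``voi_parametric.csv``,
    ``contrast.csv`` (T/N ratios), ``cutoff.json`` and ``run.log``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        config.to_yaml(outdir / "config.yaml")
        if study is None:
            log.info("generating phantom (seed=%d)", config.seed)
            study = make_phantom(
                PhantomSpec(seed=config.seed, noise_scale=config.noise_scale)
            )
        sched = study.dynamic.schedule
        weights = _fit_weights(config, sched)

        log.info("extracting image-derived input function")
        idif = extract_idif(study.dynamic, study.labels, AORTA_LABEL)

        vois = [LIVER_LABEL] + study.lesion_labels
        log.info("NLLS fits for %d VOIs x %s", len(vois), list(config.models))
        fit_rows, patlak_rows = [], []
        for lab in vois:
            tac = study.dynamic.voi_tac(study.labels, lab)
            ranked = akaike_select(tac, idif, config.model_specs, weights=weights)
            for rank, fr in enumerate(ranked):
                fit_rows.append({"label": lab, "aic_rank": rank, **fr.to_row()})
            pr = patlak_fit(tac, idif, t_star=config.t_star)
            patlak_rows.append(
                {"label": lab, "Ki": pr.ki, "Ve": pr.ve, "t_star": pr.t_star,
                 "r_squared": pr.r_squared, "n_frames_used": pr.n_used}
            )
        voi_fits = pd.DataFrame(fit_rows)
        voi_patlak = pd.DataFrame(patlak_rows)
        voi_fits.to_csv(outdir / "voi_fits.csv", index=False)
        voi_patlak.to_csv(outdir / "patlak_voi.csv", index=False)

        log.info("parametric imaging (basis 2TC-3k + Patlak)")
        maps2tc = fit_parametric(
            study.dynamic, idif, thetas=config.theta_grid(),
            vb_correction=config.vb_correction,
        )
        mapspat = patlak_voxelwise(study.dynamic, idif, t_star=config.t_star)
        maps2tc.to_nifti(outdir / "maps")
        mapspat.to_nifti(outdir / "maps")

        stats2tc = extract_voi_values(maps2tc, study.labels)
        statspat = extract_voi_values(mapspat, study.labels)
        voi_maps = pd.concat([stats2tc, statspat], ignore_index=True)
        voi_maps.to_csv(outdir / "voi_parametric.csv", index=False)

        # per-VOI SUV from the static volume closest to the configured time
        stime = min(study.static_suv, key=lambda t: abs(t - config.static_time_min))
        suv_img = study.static_suv[stime]
        suv_rows = [
            {"label": lab,
             "suv_mean": float(suv_img[study.labels == lab].mean()),
             "suv_max": float(suv_img[study.labels == lab].max()),
             "time_min": stime}
            for lab in vois
        ]
        voi_suv = pd.DataFrame(suv_rows).set_index("label")

        def map_stat(table, name, stat):
            t = table[table["map"] == name].set_index("label")[stat]
            return t

        contrast_rows = []
        quantities = {
            "SUV": (voi_suv["suv_mean"], voi_suv["suv_max"]),
            "Ki2TC": (map_stat(stats2tc, "Ki2TC", "mean"), map_stat(stats2tc, "Ki2TC", "max")),
            "KiPatlak": (map_stat(statspat, "KiPatlak", "mean"), map_stat(statspat, "KiPatlak", "max")),
        }
        for qname, (mean_t, max_t) in quantities.items():
            nmean = float(mean_t[LIVER_LABEL])
            for lab in study.lesion_labels:
                contrast_rows.append(
                    {"label": lab, "quantity": qname,
                     "tmean_nmean": tn_ratio(float(mean_t[lab]), nmean),
                     "tmax_nmean": tn_ratio(float(max_t[lab]), nmean)}
                )
        contrast = pd.DataFrame(contrast_rows)
        contrast.to_csv(outdir / "contrast.csv", index=False)

        log.info("cutoff calibration at SUV %.1f", config.suv_ref)
        lesions = study.lesion_labels
        suv_vals = voi_suv.loc[lesions, "suv_mean"].to_numpy()
        cutoffs = {}
        for qname, (mean_t, _) in quantities.items():
            if qname == "SUV":
                continue
            ki_vals = mean_t[lesions].to_numpy()
            co = calibrate_cutoff(suv_vals, ki_vals, suv_ref=config.suv_ref)
            cutoffs[qname] = {
                "ki_cutoff": co.ki_cutoff, "ki_ci": list(co.ki_ci),
                "suv_ci": list(co.suv_ci), "slope": co.slope,
                "intercept": co.intercept, "r_squared": co.r_squared, "n": co.n,
            }
        with open(outdir / "cutoff.json", "w") as fh:
            json.dump(cutoffs, fh, indent=2)

        log.info("done in %.1f s", time.time() - t0)
        return {
            "study": study,
            "idif": idif,
            "voi_fits": voi_fits,
            "voi_patlak": voi_patlak,
            "voi_parametric": voi_maps,
            "voi_suv": voi_suv.reset_index(),
            "contrast": contrast,
            "cutoffs": cutoffs,
            "maps_2tc": maps2tc,
            "maps_patlak": mapspat,
        }
    finally:
        log.removeHandler(handler)
        handler.close()


def _lesion_parametric_ki(study: PhantomStudy, config: RunConfig) -> pd.DataFrame:
    """Per-lesion mean parametric Ki (2TC + Patlak) and SUV for one visit."""
    idif = extract_idif(study.dynamic, study.labels, AORTA_LABEL)
    m2 = fit_parametric(study.dynamic, idif, thetas=config.theta_grid(),
                        vb_correction=config.vb_correction)
    mp = patlak_voxelwise(study.dynamic, idif, t_star=config.t_star)
    rows = []
    stime = min(study.static_suv, key=lambda t: abs(t - config.static_time_min))
    for lab in study.lesion_labels:
        m = study.labels == lab
        rows.append(
            {"label": lab,
             "ki_2tc": float(m2["Ki2TC"][m].mean()),
             "ki_patlak": float(mp["KiPatlak"][m].mean()),
             "suv": float(study.static_suv[stime][m].mean())}
        )
    return pd.DataFrame(rows).set_index("label")


def run_test_retest(config: RunConfig, outdir) -> dict:
    """Paired-visit study and its repeatability statistics.

    Generates two phantoms whose lesion Ki values are jittered by the
    configured within-subject CV, quantifies each visit independently
    (IDIF, parametric 2TC and Patlak Ki, SUV) and reduces the paired
    lesion values to Bland-Altman bias/limits, the relative repeatability
    coefficient (convention as configured) and the Deming line.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    s1, s2 = make_test_retest(
        PhantomSpec(seed=config.seed, noise_scale=config.noise_scale),
        wcv_pct=config.wcv_pct,
        seed=config.seed,
    )
    v1 = _lesion_parametric_ki(s1, config)
    v2 = _lesion_parametric_ki(s2, config)
    table = v1.join(v2, lsuffix="_test", rsuffix="_retest").reset_index()
    table.to_csv(outdir / "test_retest_values.csv", index=False)

    stats_rows = []
    for q in ("ki_2tc", "ki_patlak", "suv"):
        a = table[f"{q}_test"].to_numpy()
        b = table[f"{q}_retest"].to_numpy()
        ba = bland_altman(a, b)
        dem = deming_fit(a, b)
        stats_rows.append(
            {"quantity": q,
             "rc_pct": repeatability_coefficient(a, b, config.rc_convention),
             "rc_convention": config.rc_convention,
             "bias_pct": ba.bias_pct, "loa_lower": ba.loa_lower,
             "loa_upper": ba.loa_upper,
             "deming_slope": dem.slope, "deming_intercept": dem.intercept,
             "pearson_r": float(np.corrcoef(a, b)[0, 1]), "n_pairs": len(a)}
        )
    stats = pd.DataFrame(stats_rows)
    stats.to_csv(outdir / "test_retest_stats.csv", index=False)
    return {"values": table, "stats": stats, "studies": (s1, s2)}
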