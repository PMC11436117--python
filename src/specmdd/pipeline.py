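"""End-to-end pipeline: simulate (or load) -> spectra -> fit -> features ->
statistics -> classification -> correlation, as one reproducible run.

Every stage writes its table under the run directory; a manifest records the
config hash, seed and package versions so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import features as feat
from . import stats as st
from .io import write_json
from .specparam import (DEFAULT_FIT_RANGE, PeakSettings, fit_spectrum,
                        standard_bands)
from .spectra import welch_psd_median
from .synth import CohortConfig, SubjectRecord, make_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    data_dir: str | None = None       # real-data mode: load instead of simulate
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE
    fit_mode: str = "fixed"
    peak_settings: PeakSettings = field(default_factory=PeakSettings)
    seg_seconds: float = 2.0
    overlap: float = 0.5
    spaces: tuple[str, ...] = ("electrode", "source")
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), default=enc,
                       sort_keys=True).encode()).hexdigest()[:16]


def fit_cohort(cohort: list[SubjectRecord], config: RunConfig):
    """Welch-median spectra and spectral-model fits for every channel of
    every subject with signal data.  Returns (spectra, models) as nested
    dicts keyed by subject then channel."""
    spectra: dict[str, dict] = {}
    models: dict[str, dict] = {}
    for subj in cohort:
        if subj.data is None:
            continue
        spectra[subj.subject_id] = {}
        models[subj.subject_id] = {}
        for ch_label, sig in zip(subj.channel_labels, subj.data):
            ps = welch_psd_median(np.asarray(sig, dtype=float),
                                  config.cohort.sfreq, config.seg_seconds,
                                  config.overlap, channel_label=ch_label)
            spectra[subj.subject_id][ch_label] = ps
            models[subj.subject_id][ch_label] = fit_spectrum(
                ps, fit_range=config.fit_range, mode=config.fit_mode,
                peak_settings=config.peak_settings)
    return spectra, models


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages and write the report files under ``out_dir``.

    Outputs: feature_table.csv, battery.csv, classification.json,
    correlations.csv and manifest.json.  Any stage failure raises with the
    stage name; files already written are kept.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.data_dir:
            from .io import read_cohort
            cohort = read_cohort(config.data_dir)
        else:
            cohort = make_cohort(dataclasses.replace(config.cohort,
                                                     seed=config.seed))
        stage = "spectra/fit"
        spectra, models = fit_cohort(cohort, config)
        stage = "features"
        bands = [b for b in standard_bands() if b.name in feat.ANALYSIS_BANDS]
        table = feat.build_feature_table(cohort, models, spectra,
                                         bands=bands, spaces=config.spaces)
        feat.write_feature_table(table, out / "feature_table.csv")
        stage = "stats"
        design = st.BatteryDesign(spaces=config.spaces)
        battery = st.run_battery(table, design, alpha=config.alpha)
        st.battery_frame(battery, alpha=config.alpha).to_csv(
            out / "battery.csv", index=False)
        stage = "classify"
        results = clf.run_menu(table, n_boot=config.n_boot, seed=config.seed)
        menu = clf.enumerate_feature_sets()
        payload = []
        for spec, res in zip(menu, results):
            d = res.to_dict()
            d["n_features"] = len(spec.keys)
            d["kind"] = spec.kind
            payload.append(d)
        write_json(payload, out / "classification.json")
        stage = "correlate"
        corr = st.correlation_table(table, list(clf.SELECTED_FEATURES.values()))
        corr.to_csv(out / "correlations.csv", index=False)
        stage = "manifest"
        import specmdd
        write_json({"config_hash": config.digest(), "seed": config.seed,
                    "bonferroni_family_size": design.family_size,
                    "alpha": config.alpha,
                    "n_subjects": len(cohort),
                    "versions": {"specmdd": specmdd.__version__,
                                 "numpy": np.__version__,
                                 "pandas": pd.__version__}},
                   out / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def write_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed (or partial) run."""
    run_dir = Path(run_dir)
    lines = ["specmdd run report", "=" * 40]

    bpath = run_dir / "battery.csv"
    if bpath.exists():
        battery = pd.read_csv(bpath)
        if battery.empty:
            lines.append("Group battery: zero tests")
        else:
            lines.append(f"Group battery: {len(battery)} tests "
                         f"(Bonferroni family {len(battery)})")
            top = battery.reindex(
                battery["hedges_g"].abs().sort_values(ascending=False).index
            ).head(5)
            lines.append("Top rows by |Hedge's g|:")
            for _, r in top.iterrows():
                lines.append(f"  {r['feature']:45s} g={r['hedges_g']:+.2f} "
                             f"p_adj={r['p_bonferroni']:.3g}"
                             f"{' *' if r['significant_at_0.05'] else ''}")
    else:
        lines.append("Group battery: absent")

    cpath = run_dir / "classification.json"
    if cpath.exists():
        results = json.loads(cpath.read_text())
        if results:
            best = max(results, key=lambda r: r["auc"])
            lines.append(f"Best feature set by AUC: {best['name']} "
                         f"(AUC={best['auc']:.2f}, "
                         f"95% CI [{best['ci95'][0]:.2f}, {best['ci95'][1]:.2f}], "
                         f"{best['n_features']} features)")
    else:
        lines.append("Classification: absent")

    rpath = run_dir / "correlations.csv"
    if rpath.exists():
        corr = pd.read_csv(rpath)
        lines.append(f"Correlations with clinical scores ({len(corr)} rows):")
        for _, r in corr.iterrows():
            lines.append(f"  {r['feature']:45s} vs {r['score']:8s} "
                         f"rho={r['rho']:+.2f} p={r['p']:.3g}")
    else:
        lines.append("Correlations: absent")

    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
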