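"""End-to-end study workflow.

Order of stages mirrors the study protocol: per-tissue PCA Q-residual
outlier screening on the raw full-range spectra, then per-region
cut / baseline / area-normalize / second-derivative preprocessing, then
per-tissue PLS of age on each region, pooled-tissue PCA per region,
the nine-band biomarker panel, and two-way ANOVA with Sidak contrasts
per index.  Everything is deterministic given (input, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import band_indices, chemometrics, group_stats, preprocess
from .chemometrics import CVSpec, DataMatrix
from .errors import DegenerateDataError, FtirError, GroupError, RankError
from .io_spectra import SpectraSet, write_spectra_csv
from .preprocess import CANONICAL_REGIONS, RegionSpec, SGParams

#: Minimum |training correlation| below which a PLS fit is reported as
#: non-informative (spectra carry no usable age signal).
MIN_INFORMATIVE_R = 0.3


@dataclass
class PipelineConfig:
    """All analysis settings in one place.

    The Savitzky-Golay second-derivative window defaults to 11 points
    (22 cm^-1 at the default 2 cm^-1 grid): differentiation amplifies
    white noise by ~sqrt(6)/step^2 at the minimal 3-point window, and an
    11-point quadratic window keeps the small Amide I sub-bands readable
    at realistic noise while still resolving bands 11 cm^-1 apart.
    Narrower windows (3 = the plain central difference, 5, 7, 9) are
    available for cross-checks and low-noise data.

    ``replicates`` controls whether technical replicates enter PCA/PLS
    as independent rows ("rows") or are averaged per animal ("average").
    Band-intensity indices and ANOVA always work per animal (technical
    replicates averaged) to avoid pseudoreplication.
    """

    regions: Mapping[str, RegionSpec] = field(
        default_factory=lambda: dict(CANONICAL_REGIONS)
    )
    baseline_method: str = "rubberband"
    sg: SGParams = field(default_factory=lambda: SGParams(window_points=11))
    outlier_rule: str = "mad"
    outlier_k: float = 3.5
    cv_folds: int = 10
    max_factors: int = 7
    peak_halfwidth: float = band_indices.DEFAULT_HALFWIDTH
    replicates: str = "rows"
    young_age: int = 6
    old_age: int = 24
    alpha: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = {k: dataclasses.asdict(v) for k, v in self.regions.items()}
        d["sg"] = dataclasses.asdict(self.sg)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _average_technical_replicates(spectra_set: SpectraSet) -> SpectraSet:
    """Collapse technical replicates to one mean spectrum per animal."""
    from .io_spectra import SampleMeta, Spectrum

    groups: dict[tuple, list] = {}
    for s in spectra_set:
        key = (s.meta.tissue, s.meta.age_months, s.meta.bio_rep)
        groups.setdefault(key, []).append(s)
    out = []
    for (tissue, age, bio), members in groups.items():
        mean_abs = np.mean([m.absorbance for m in members], axis=0)
        sid = f"{tissue[:4]}-{age:02d}M-b{bio:02d}-avg"
        out.append(
            Spectrum(
                members[0].wavenumbers.copy(),
                mean_abs,
                SampleMeta(sid, tissue, age, bio, 1),
            )
        )
    return SpectraSet(out)


def screen_outliers(
    spectra_set: SpectraSet,
    rule: str,
    k: float,
    max_components: int = 7,
    structure_evr: float = 0.10,
) -> tuple[SpectraSet, list[str]]:
    """Per-tissue PCA on raw full-range spectra; drop high-Q samples.

    The screening model keeps only strong structural components (each
    explaining at least ``structure_evr`` of the variance, capped at
    ``max_components``).  A model with too many components absorbs the
    very artifacts Q-residuals are meant to expose — any single-sample
    deviation can become its own component — while gross corruption is
    assumed to have been caught earlier by visual inspection, as is
    routine during acquisition.
    """
    removed: list[str] = []
    kept = []
    meta = spectra_set.meta_frame()
    for tissue in sorted(meta["tissue"].unique()):
        sub = spectra_set.filter(tissue=tissue)
        data = DataMatrix.from_spectra(sub)
        cap = min(max_components, data.n_rows - 1, data.X.shape[1])
        try:
            full = chemometrics.pca_fit(data, cap)
            ncomp = int(np.sum(full.explained_variance_ratio >= structure_evr))
            ncomp = max(1, min(ncomp, cap))
            model = (
                full
                if ncomp == cap
                else chemometrics.pca_fit(data, ncomp)
            )
        except RankError:
            # rank-deficient (e.g. identical spectra): nothing to screen
            kept.extend(sub)
            continue
        q = chemometrics.q_residuals(model, data)
        flags = chemometrics.flag_outliers(q, rule=rule, k=k)
        for s, f in zip(sub, flags):
            if f:
                removed.append(s.meta.sample_id)
            else:
                kept.append(s)
    return SpectraSet(kept), sorted(removed)


def pls_age_analysis(
    derived: SpectraSet,
    config: PipelineConfig,
    seed: int,
    young: int,
    old: int,
) -> dict:
    """PLS of age on one tissue's second-derivative region.

    Returns the CV curve, selected factor count, training correlation,
    and young-vs-old score discrimination.  Discrimination is computed
    on *out-of-fold* predicted ages (centered on the cohort mean
    prediction) at the selected factor count, not on training scores:
    a PLS factor is built from the X'y covariance, so training scores
    separate the age groups even on pure noise, while cross-validated
    scores stay calibrated (null data give ~chance discrimination).
    """
    data = DataMatrix.from_spectra(derived)
    ages = data.row_meta["age_months"].to_numpy(float)
    animals = (
        data.row_meta["tissue"].astype(str)
        + "/"
        + data.row_meta["age_months"].astype(str)
        + "/"
        + data.row_meta["bio_rep"].astype(str)
    ).to_numpy()
    n_groups = len(set(animals))
    model = chemometrics.pls_fit(
        data,
        ages,
        max_factors=config.max_factors,
        cv=CVSpec(n_folds=min(config.cv_folds, n_groups), seed=seed),
        groups=animals,
    )
    a_sel = model.n_factors
    cv_pred = model.y_cv[:, a_sel - 1]
    try:
        r_cv = (
            chemometrics.pearson_r(ages, cv_pred)
            if not np.any(np.isnan(cv_pred))
            else float("nan")
        )
    except DegenerateDataError:
        r_cv = float("nan")
    # training R is always optimistic; the CV correlation decides whether
    # the region carries a real age signal
    informative = np.isfinite(r_cv) and r_cv >= MIN_INFORMATIVE_R

    extreme = data.row_meta["age_months"].isin([young, old]).to_numpy()
    labels = data.row_meta["age_months"].to_numpy()[extreme]
    best = None
    if not np.any(np.isnan(cv_pred)):
        scores = cv_pred[extreme] - float(np.mean(cv_pred))
        try:
            best = chemometrics.score_discrimination(
                scores, labels, positive_group=old, factor_index=a_sel,
                orient="fixed",
            )
        except GroupError:
            best = None
    return {
        "n_rows": data.n_rows,
        "cv_rmse": [float(v) for v in model.cv_rmse],
        "selected_factors": int(model.n_factors),
        "pearson_r": float(model.pearson_r),
        "pearson_r_cv": float(r_cv),
        "informative": bool(informative),
        "discrimination": None if best is None else _disc_dict(best),
        "model": model,
    }


def _disc_dict(res: chemometrics.DiscriminationResult) -> dict:
    return {
        "factor_index": int(res.factor_index),
        "positive_group": res.positive_group,
        "threshold": float(res.threshold),
        "tp": res.tp,
        "fn": res.fn,
        "tn": res.tn,
        "fp": res.fp,
        "flipped": bool(res.flipped),
        "sensitivity": float(res.sensitivity),
        "specificity": float(res.specificity),
    }


def compare_tissues_pca(derived: SpectraSet, positive_group: str = "cardiac") -> dict:
    """PC1 separation of the two tissues on pooled second-derivative spectra."""
    data = DataMatrix.from_spectra(derived)
    tissues = data.row_meta["tissue"].unique()
    if len(tissues) < 2:
        raise GroupError("tissue comparison needs both tissues")
    ncomp = min(7, data.n_rows - 1, data.X.shape[1])
    model = chemometrics.pca_fit(data, ncomp)
    res = chemometrics.score_discrimination(
        model.scores[:, 0],
        data.row_meta["tissue"].to_numpy(),
        positive_group=positive_group,
        factor_index=1,
    )
    out = _disc_dict(res)
    out["explained_variance_ratio_pc1"] = float(model.explained_variance_ratio[0])
    return out


def run_pipeline(
    spectra_set: SpectraSet,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full workflow and return the study report (JSON-able).

    When ``out_dir`` is given, per-stage CSV artifacts and the report are
    written there.
    """
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": int(seed),
        "n_input_spectra": len(spectra_set),
    }

    # 1. outlier screening on raw full-range spectra, per tissue
    clean, removed = screen_outliers(
        spectra_set, config.outlier_rule, config.outlier_k
    )
    report["outliers_removed"] = removed
    report["n_spectra_after_qc"] = len(clean)

    analysis_set = (
        _average_technical_replicates(clean)
        if config.replicates == "average"
        else clean
    )

    # 2. preprocessing per region
    normalized: dict[str, SpectraSet] = {}
    derived: dict[str, SpectraSet] = {}
    for name, region in config.regions.items():
        norm, der = preprocess.preprocess_region(
            analysis_set, region, config.baseline_method, config.sg
        )
        normalized[name], derived[name] = norm, der

    # 3. PLS of age per tissue per region
    tissues = sorted(analysis_set.meta_frame()["tissue"].unique())
    report["pls"] = {}
    models = {}
    for tissue in tissues:
        report["pls"][tissue] = {}
        for name in config.regions:
            sub = derived[name].filter(tissue=tissue)
            try:
                res = pls_age_analysis(
                    sub, config, seed, config.young_age, config.old_age
                )
            except (DegenerateDataError, GroupError, RankError) as exc:
                report["pls"][tissue][name] = {"error": str(exc)}
                continue
            models[(tissue, name)] = res.pop("model")
            report["pls"][tissue][name] = res

    # 4. pooled-tissue PCA per region
    report["tissue_pca"] = {}
    for name in config.regions:
        try:
            report["tissue_pca"][name] = compare_tissues_pca(derived[name])
        except (GroupError, DegenerateDataError, RankError) as exc:
            report["tissue_pca"][name] = {"error": str(exc)}

    # 5. biomarker panel + statistics, always on animal-mean spectra:
    #    technical replicates are repeat measurements of one specimen, so
    #    they are averaged before peak extraction (better-conditioned
    #    derivative peaks) and the panel has one row per animal
    if not all(k in config.regions for k in ("lipid", "amide", "fingerprint")):
        report["panel_summary"] = {
            "error": "panel needs the lipid, amide and fingerprint regions"
        }
        report["anova"] = {}
        report["comparisons"] = {}
        if out_dir is not None:
            _write_artifacts(out_dir, report, clean, normalized, derived, None, None)
        return report

    animal_set = (
        analysis_set
        if config.replicates == "average"
        else _average_technical_replicates(clean)
    )
    panel_normalized: dict[str, SpectraSet] = {}
    panel_derived: dict[str, SpectraSet] = {}
    for name in ("lipid", "amide", "fingerprint"):
        norm, der = preprocess.preprocess_region(
            animal_set, config.regions[name], config.baseline_method, config.sg
        )
        panel_normalized[name], panel_derived[name] = norm, der
    panel = band_indices.compute_panel(
        panel_derived["lipid"],
        panel_derived["amide"],
        panel_derived["fingerprint"],
        panel_normalized["amide"],
        halfwidth=config.peak_halfwidth,
    )
    animal_panel = panel
    summary = band_indices.summarize_panel(panel)
    report["panel_summary"] = summary.to_dict(orient="records")

    report["anova"] = {}
    report["comparisons"] = {}
    for index in band_indices.INDEX_NAMES:
        vals = animal_panel[index].to_numpy()
        t = animal_panel["tissue"].to_numpy()
        a = animal_panel["age_months"].to_numpy()
        try:
            table = group_stats.two_way_anova(vals, t, a)
            comps = group_stats.pairwise_cells(vals, t, a, alpha=config.alpha)
        except (DegenerateDataError, GroupError) as exc:
            report["anova"][index] = {"error": str(exc)}
            report["comparisons"][index] = {"error": str(exc)}
            continue
        report["anova"][index] = table.reset_index().to_dict(orient="records")
        report["comparisons"][index] = comps.to_dict(orient="records")

    if out_dir is not None:
        _write_artifacts(out_dir, report, clean, normalized, derived, panel, summary)
    return report


def _write_artifacts(out_dir, report, clean, normalized, derived, panel, summary):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if panel is not None:
        panel.to_csv(out / "panel.csv", index=False)
        summary.to_csv(out / "panel_summary.csv", index=False)
    for name, spectra in normalized.items():
        write_spectra_csv(spectra, out / f"normalized_{name}.csv")
    for name, spectra in derived.items():
        write_spectra_csv(spectra, out / f"derived_{name}.csv")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "summary.txt").write_text(render_summary(report))


def render_summary(report: dict) -> str:
    """Human-readable digest of a study report."""
    lines = [
        f"ftirage study report (config {report['config_hash']}, seed {report['seed']})",
        f"input spectra: {report['n_input_spectra']}; "
        f"after QC: {report['n_spectra_after_qc']} "
        f"({len(report['outliers_removed'])} outliers removed)",
        "",
        "PLS of age on second-derivative spectra:",
    ]
    for tissue, regions in report.get("pls", {}).items():
        for region, res in regions.items():
            if "error" in res:
                lines.append(f"  {tissue:9s} {region:12s} ERROR: {res['error']}")
                continue
            d = res["discrimination"]
            disc = (
                f"factor {d['factor_index']}: sens {d['sensitivity']:.1f}% / "
                f"spec {d['specificity']:.1f}%"
                if d
                else "no discrimination"
            )
            flag = "" if res["informative"] else "  [non-informative]"
            lines.append(
                f"  {tissue:9s} {region:12s} R={res['pearson_r']:+.3f} "
                f"({res['selected_factors']} factor"
                f"{'s' if res['selected_factors'] != 1 else ''}){flag}; "
                f"young-vs-old {disc}"
            )
    lines.append("")
    lines.append("Tissue separation by PC1 (pooled spectra):")
    for region, res in report.get("tissue_pca", {}).items():
        if "error" in res:
            lines.append(f"  {region:12s} ERROR: {res['error']}")
        else:
            lines.append(
                f"  {region:12s} sens {res['sensitivity']:.1f}% / "
                f"spec {res['specificity']:.1f}% "
                f"(PC1 {100 * res['explained_variance_ratio_pc1']:.1f}% var)"
            )
    lines.append("")
    lines.append("Sidak-significant cardiac-vs-skeletal contrasts:")
    for index, comps in report.get("comparisons", {}).items():
        if isinstance(comps, dict) and "error" in comps:
            continue
        sig = [c for c in comps if c["significant"]]
        if sig:
            ages = ", ".join(f"{c['age_months']}M {c['stars']}" for c in sig)
            lines.append(f"  {index}: {ages}")
    return "\n".join(lines) + "\n"
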