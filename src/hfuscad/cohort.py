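"""Cohort fixtures, cohort simulation, and end-to-end pipeline orchestration.

The packaged fixture tables summarize the 45-animal study cohort: joint
(group x SSS x CUS) counts, per-(group, SSS) hepatorenal-index statistics,
and per-group phenotype means.  ``simulate_cohort`` turns them back into
per-animal records, either exactly (one subject per count cell) or by
group-conditional multinomial resampling; ``run_pipeline`` optionally
attaches simulated B-mode frames per subject, measures HRI and the four
GLCM features on them, and assembles the screening, correlation and summary
tables of the study's statistical analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from hfuscad.echogenicity import hri_from_image
from hfuscad.preprocess import PreprocessParams, preprocess_roi
from hfuscad.scoring import (
    bonferroni_alpha,
    classify_by_cutoff,
    cus_positive,
    derive_cutoff,
    indeterminate_zone,
    minmax_normalize,
    percent_change,
    screening_metrics,
    spearman,
    sss_class,
)
from hfuscad.speckle import default_layout, make_tissue_map, params_for_grade, \
    simulate_bmode, standard_rois
from hfuscad.texture import build_glcm, features_for_subject, texture_features

GROUPS = ("WT_SD", "KO_SD", "WT_WD", "KO_WD")
GROUP_SIZES = {"WT_SD": 7, "KO_SD": 7, "WT_WD": 16, "KO_WD": 15}
FEATURE_COLUMNS = ("contrast", "correlation", "energy", "sum_entropy")


class FixtureIntegrityError(ValueError):
    """Raised when the packaged tables fail their count checks."""


@dataclass
class CohortFixture:
    table1: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame


def _data_path(name: str) -> Path:
    return Path(resources.files("hfuscad.data") / name)


def load_fixtures() -> CohortFixture:
    """Load and validate the packaged summary tables."""
    t1 = pd.read_csv(_data_path("table1_phenotype.csv"))
    t3 = pd.read_csv(_data_path("table3_cus_by_sss.csv"))
    t4 = pd.read_csv(_data_path("table4_hri_by_sss.csv"))
    total = int(t3["count"].sum())
    if total != 45:
        raise FixtureIntegrityError(f"cohort counts sum to {total}, not 45")
    sizes = t3.groupby("group")["count"].sum().to_dict()
    if sizes != GROUP_SIZES:
        raise FixtureIntegrityError(f"group sizes {sizes} != {GROUP_SIZES}")
    # every (group, SSS) cell of the count table needs an HRI distribution
    have = set(zip(t4["group"], t4["sss_total"]))
    need = set(zip(t3["group"], t3["sss_total"]))
    if not need <= have:
        raise FixtureIntegrityError(
            f"missing HRI cells: {sorted(need - have)}")
    return CohortFixture(t1, t3, t4)


# ---------------------------------------------------------------------------
# synthetic subjects

@dataclass
class SyntheticSubject:
    subject: str
    genotype: str          # WT or KO
    diet: str              # SD or WD
    group: str
    age_weeks: int
    sss_macro: int
    sss_micro: int
    sss_hypertrophy: int
    cus_parenchyma: int
    cus_relative: int
    cus_ascites: int
    hri: float
    severity_class: int
    grade: int             # simulator grade (= severity class code)
    features: dict = field(default_factory=dict)

    @property
    def sss_total(self) -> int:
        return self.sss_macro + self.sss_micro + self.sss_hypertrophy

    @property
    def cus_total(self) -> int:
        return self.cus_parenchyma + self.cus_relative + self.cus_ascites


def split_sss(total: int) -> tuple[int, int, int]:
    """Deterministic SSS component split: fill macrovesicular, then
    microvesicular, then hypertrophy, each capped at 3."""
    macro = min(3, total)
    micro = min(3, total - macro)
    hyper = total - macro - micro
    if hyper > 3:
        raise ValueError("SSS total must be <= 9")
    return macro, micro, hyper


def split_cus(total: int) -> tuple[int, int, int]:
    """Deterministic CUS component split: parenchyma (<=3), then relative
    echogenicity (<=2), then ascites."""
    par = min(3, total)
    rel = min(2, total - par)
    asc = total - par - rel
    if asc > 1:
        raise ValueError("CUS total must be <= 6")
    return par, rel, asc


def _draw_hri(row, rng: np.random.Generator) -> float:
    mean, sd = row["hri_mean"], row["hri_sd"]
    if int(row["n"]) == 1 or pd.isna(sd) or sd == 0:
        return float(mean)
    if int(row["inconsistent"]):
        # printed range contradicts the printed mean; sample untruncated
        return float(rng.normal(mean, sd))
    a = (row["hri_min"] - mean) / sd
    b = (row["hri_max"] - mean) / sd
    return float(sstats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                      random_state=rng))


def _make_subject(idx, group, cus_total, sss_total, hri) -> SyntheticSubject:
    genotype, diet = group.split("_")
    macro, micro, hyper = split_sss(int(sss_total))
    par, rel, asc = split_cus(int(cus_total))
    cls = sss_class(int(sss_total))
    return SyntheticSubject(
        subject=f"M{idx:03d}", genotype=genotype, diet=diet, group=group,
        age_weeks=24, sss_macro=macro, sss_micro=micro, sss_hypertrophy=hyper,
        cus_parenchyma=par, cus_relative=rel, cus_ascites=asc,
        hri=hri, severity_class=cls.code, grade=cls.code,
    )


def simulate_cohort(fixture: CohortFixture | None = None, mode: str = "exact",
                    n: int | None = None, seed: int = 0) -> list[SyntheticSubject]:
    """Rebuild a per-animal cohort from the fixture tables.

    ``exact`` emits one subject per count-cell occurrence (45 subjects, in a
    fixed order); ``resample`` draws ``n`` subjects from group-conditional
    multinomials over the observed (CUS, SSS) cells, allocating group sizes
    proportionally.  HRI is drawn from a truncated normal with the subject's
    (group, SSS) cell statistics in both modes.
    """
    if fixture is None:
        fixture = load_fixtures()
    rng = np.random.default_rng(seed)
    t3 = fixture.table3.sort_values(["group", "sss_total", "cus_total"],
                                    key=lambda s: s.map(
                                        {g: i for i, g in enumerate(GROUPS)})
                                    if s.name == "group" else s)
    t4 = fixture.table4.set_index(["group", "sss_total"])

    cells: list[tuple[str, int, int]] = []
    if mode == "exact":
        for _, row in t3.iterrows():
            cells += [(row["group"], row["cus_total"], row["sss_total"])] \
                * int(row["count"])
    elif mode == "resample":
        if n is None or n < 4:
            raise ValueError("resample mode needs n >= 4 (one per group)")
        quota = _proportional_allocation(n)
        for group in GROUPS:
            sub = t3[t3["group"] == group]
            probs = sub["count"].to_numpy(float)
            probs /= probs.sum()
            draws = rng.multinomial(quota[group], probs)
            for (_, row), k in zip(sub.iterrows(), draws):
                cells += [(group, row["cus_total"], row["sss_total"])] * int(k)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    subjects = []
    for idx, (group, cus_total, sss_total) in enumerate(cells, start=1):
        hri = _draw_hri(t4.loc[(group, sss_total)], rng)
        subjects.append(_make_subject(idx, group, cus_total, sss_total, hri))
    return subjects


def _proportional_allocation(n: int) -> dict[str, int]:
    """Largest-remainder allocation of ``n`` across groups, proportional to
    the study group sizes."""
    raw = {g: n * GROUP_SIZES[g] / 45.0 for g in GROUPS}
    base = {g: int(np.floor(v)) for g, v in raw.items()}
    short = n - sum(base.values())
    for g in sorted(GROUPS, key=lambda g: raw[g] - base[g], reverse=True)[:short]:
        base[g] += 1
    return base


# ---------------------------------------------------------------------------
# image measurement

def measure_simulated_image(image, layout, pre_params: PreprocessParams | None = None):
    """HRI and lobe-averaged texture features for one simulated frame.

    The four liver disks stand in for the per-lobe images of a scanning
    session; features are extracted with the standard preprocessing chain
    and averaged per subject; HRI uses the liver/renal-cortex disk means.
    """
    if pre_params is None:
        pre_params = PreprocessParams()
    liver_rois, cortex_roi = standard_rois(layout)
    feats = []
    liver_means = []
    for roi in liver_rois:
        lv = preprocess_roi(image, roi, pre_params)
        feats.append(texture_features(build_glcm(
            lv.levels, lv.mask, n_gray_levels=lv.n_gray_levels)))
        rows, cols = zip(*roi.pixel_set)
        liver_means.append(float(image.pixels[list(rows), list(cols)].mean()))
    rows, cols = zip(*cortex_roi.pixel_set)
    renal_mean = float(image.pixels[list(rows), list(cols)].mean())
    hri = float(np.mean(liver_means)) / renal_mean
    return hri, features_for_subject(feats)


def attach_image_measurements(subjects: list[SyntheticSubject], seed: int = 0,
                              size: int = 256) -> None:
    """Simulate one frame per subject (grade = severity class) and store the
    measured HRI and texture features on ``subject.features`` in place."""
    layout = default_layout(size)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(subjects))
    for subject, child in zip(subjects, children):
        rng = np.random.default_rng(child)
        params = params_for_grade(subject.grade, seed=seed)
        tissue = make_tissue_map(params, layout, rng=rng)
        image = simulate_bmode(tissue, params, rng=rng)
        hri, feats = measure_simulated_image(image, layout)
        subject.features = {
            "hri_measured": hri,
            "contrast": feats.contrast,
            "correlation": feats.correlation,
            "energy": feats.energy,
            "sum_entropy": feats.sum_entropy,
        }


def cohort_to_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "subject": s.subject, "genotype": s.genotype, "diet": s.diet,
            "group": s.group, "age_weeks": s.age_weeks,
            "cus_parenchyma": s.cus_parenchyma, "cus_relative": s.cus_relative,
            "cus_ascites": s.cus_ascites, "cus_total": s.cus_total,
            "sss_macro": s.sss_macro, "sss_micro": s.sss_micro,
            "sss_hypertrophy": s.sss_hypertrophy, "sss_total": s.sss_total,
            "severity_class": s.severity_class, "hri": s.hri,
        }
        row.update(s.features)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summaries

def steatosis_prevalence(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-group steatotic fraction (SSS total >= 1)."""
    out = []
    for group, sub in frame.groupby("group", sort=False):
        pos = int((sub["sss_total"] >= 1).sum())
        out.append({"group": group, "n": len(sub), "steatotic": pos,
                    "prevalence_pct": 100.0 * pos / len(sub)})
    return pd.DataFrame(out).set_index("group").loc[list(GROUPS)].reset_index()


def phenotype_summary(fixture: CohortFixture | None = None) -> pd.DataFrame:
    """Western-diet vs standard-diet percent changes per genotype for
    body-weight gain, energy intake and feed efficiency ratio."""
    if fixture is None:
        fixture = load_fixtures()
    t1 = fixture.table1.set_index(["variable", "group"])["mean"]
    rows = []
    for variable in ("bw_gain", "energy_intake", "fer"):
        for genotype in ("WT", "KO"):
            ref = t1[(variable, f"{genotype}_SD")]
            test = t1[(variable, f"{genotype}_WD")]
            rows.append({
                "variable": variable, "genotype": genotype,
                "sd_mean": ref, "wd_mean": test,
                "percent_change": round(percent_change(ref, test), 1),
            })
    return pd.DataFrame(rows)


def _correlations(frame: pd.DataFrame, predictors, m: int) -> pd.DataFrame:
    rows = []
    for name in predictors:
        res = spearman(frame[name].to_numpy(), frame["severity_class"].to_numpy(),
                       n_tests=m)
        rows.append({"predictor": name, "r": res.r, "n": res.n,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "p": res.p, "alpha": res.alpha,
                     "significant": res.significant})
    return pd.DataFrame(rows)


def run_pipeline(seed: int = 0, mode: str = "exact", n: int | None = None,
                 with_images: bool = True, out_dir=None) -> dict:
    """End-to-end analysis: cohort simulation, optional image simulation and
    measurement, screening, correlations, and report tables.

    Returns a dict of DataFrames (plus scalars) and, when ``out_dir`` is
    given, writes them as CSV along with a plain-text summary.
    """
    fixture = load_fixtures()
    subjects = simulate_cohort(fixture, mode=mode, n=n, seed=seed)
    if with_images:
        attach_image_measurements(subjects, seed=seed)
    frame = cohort_to_frame(subjects)

    truth = (frame["sss_total"] >= 1).to_numpy()
    cus_pred = np.array([cus_positive(int(t)) for t in frame["cus_total"]])
    cus_screen = screening_metrics(truth, cus_pred)

    hri = frame["hri"].to_numpy()
    cutoff = derive_cutoff(hri, ~truth)
    hri_screen = screening_metrics(truth, classify_by_cutoff(hri, cutoff))
    zone = indeterminate_zone(hri, truth)

    mild_mask = frame["severity_class"].to_numpy() == 1
    advanced = frame["severity_class"].to_numpy() >= 2
    staged = frame[mild_mask | advanced]
    stage_cutoff = derive_cutoff(staged["hri"].to_numpy(),
                                 staged["severity_class"].to_numpy() == 1)
    stage_screen = screening_metrics(
        staged["severity_class"].to_numpy() >= 2,
        classify_by_cutoff(staged["hri"].to_numpy(), stage_cutoff))

    m = 6  # CUS, HRI, and the four GLCM features
    predictors = ["cus_total", "hri"]
    if with_images:
        predictors += list(FEATURE_COLUMNS)
    correlations = _correlations(frame, predictors, m)

    crosstab = pd.crosstab(frame["cus_total"], frame["sss_total"])
    hri_by_class = frame.groupby("severity_class")["hri"].agg(
        ["count", "mean", "std", "min", "max"]).reset_index()

    normalized = None
    if with_images:
        rows = []
        for name in FEATURE_COLUMNS:
            norm, _ = minmax_normalize(frame[name].to_numpy())
            for present, label in ((truth, "steatosis"),
                                   (~truth, "no steatosis")):
                rows.append({
                    "feature": name, "histology": label,
                    "n": int(present.sum()),
                    "median": float(np.median(norm[present])),
                    "mean": float(np.mean(norm[present])),
                    "min": float(np.min(norm[present])),
                    "max": float(np.max(norm[present])),
                })
        normalized = pd.DataFrame(rows)

    report = {
        "cohort": frame,
        "screening_cus": cus_screen,
        "screening_hri": hri_screen,
        "screening_hri_staging": stage_screen,
        "hri_cutoff": cutoff,
        "hri_staging_cutoff": stage_cutoff,
        "indeterminate_zone": zone,
        "correlations": correlations,
        "alpha_threshold": bonferroni_alpha(0.05, m),
        "crosstab_cus_sss": crosstab,
        "hri_by_class": hri_by_class,
        "normalized_features": normalized,
        "prevalence": steatosis_prevalence(frame),
        "phenotype": phenotype_summary(fixture),
    }
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _screen_row(name, s):
    return (f"{name}: TP={s.tp} FP={s.fp} TN={s.tn} FN={s.fn} "
            f"sensitivity={s.sensitivity:.3f} specificity={s.specificity:.3f} "
            f"accuracy={s.accuracy:.3f} ppv={s.ppv:.3f}")


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for key in ("cohort", "correlations", "hri_by_class", "prevalence",
                "phenotype", "normalized_features"):
        if report[key] is not None:
            report[key].to_csv(out_dir / f"{key}.csv", index=False,
                               float_format="%.6g")
    report["crosstab_cus_sss"].to_csv(out_dir / "crosstab_cus_sss.csv")
    lines = [
        "Cohort analysis summary",
        "=======================",
        f"subjects: {len(report['cohort'])}",
        f"Bonferroni-adjusted significance threshold (m=6): "
        f"{report['alpha_threshold']:.5f}",
        _screen_row("CUS >= 1 vs SSS >= 1", report["screening_cus"]),
        _screen_row(f"HRI > {report['hri_cutoff']:.3f} vs SSS >= 1",
                    report["screening_hri"]),
        _screen_row(f"HRI > {report['hri_staging_cutoff']:.3f} "
                    "(mild vs moderate-severe)",
                    report["screening_hri_staging"]),
        "indeterminate HRI zone: "
        f"({report['indeterminate_zone'][0]:.3f}, "
        f"{report['indeterminate_zone'][1]:.3f})"
        + (" [empty]" if report["indeterminate_zone"][2] else ""),
    ]
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
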