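"""End-to-end seeded synthetic study: cohort, phantoms, clustering, statistics.

``run_study`` replays the full analysis chain on synthetic data: generate a
covariate cohort whose tract FA follows the forward linear model, build
streamline phantoms per subject, segment them by subset-and-consensus Ward
clustering, rasterize tracts to extract per-subject mean FA and volume,
construct ICV-matched pairs, and run the mean-centered regression /
permutation / BH statistical layer. All stage seeds derive from one master
seed by a counter-based fan-out, so identical configs give byte-identical
JSON summaries and stages can be rerun independently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import clustering, io, stats, synthetic, tracts


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are left on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ClusteringParams:
    k: int = 8
    subset_size: int = 500
    n_repetitions: int = 10
    stability_min: float = 0.5
    n_streamlines: int = 100
    radius: float = 2.0
    n_cluster_subjects: int = 3


@dataclass
class StatsParams:
    terms: Tuple[str, ...] = ("icv", "age", "sex")
    families: Tuple[str, ...] = ("icv", "sex", "age")
    alpha: float = 0.05
    n_perm: int = 500
    match_tolerance_ml: float = 10.0


@dataclass
class StudyConfig:
    cohort: synthetic.CohortSpec = field(default_factory=synthetic.CohortSpec)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    stats: StatsParams = field(default_factory=StatsParams)
    simulate_images: bool = True
    seed: int = 0
    out_dir: str = "study_out"

    @classmethod
    def desk_scale(cls, seed: int = 0, out_dir: str = "study_out") -> "StudyConfig":
        """Small configuration that exercises every stage in minutes."""
        cohort = synthetic.CohortSpec(n_men=30, n_women=30)
        return cls(cohort=cohort, seed=seed, out_dir=out_dir)

    @classmethod
    def from_json(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        cohort_raw = raw.get("cohort", {})
        if "age_range" in cohort_raw:
            cohort_raw["age_range"] = tuple(cohort_raw["age_range"])
        cfg = cls(
            cohort=synthetic.CohortSpec(**cohort_raw),
            clustering=ClusteringParams(**raw.get("clustering", {})),
            stats=StatsParams(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw.get("stats", {}).items()
                }
            ),
            simulate_images=raw.get("simulate_images", True),
            seed=int(raw["seed"]),
            out_dir=raw.get("out_dir", "study_out"),
        )
        return cfg


def derive_seeds(master_seed: int, n: int = 8) -> np.ndarray:
    """Counter-based fan-out of stage seeds from one master seed (< 2^31)."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def _phantom_grid(scale: float = 60.0) -> tracts.Grid:
    # covers the archetype curves (roughly +/- 2.4 * scale) with margin
    spacing = 8.0
    extent = int(np.ceil(2 * 3.0 * scale / spacing))
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = -3.0 * scale
    return tracts.Grid(shape=(extent, extent, extent), affine=affine)


def run_study(config: StudyConfig) -> Dict:
    """Execute the full synthetic study; returns the JSON-ready summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    summary: Dict = {
        "seed": int(config.seed),
        "stage_seeds": [int(s) for s in seeds],
        "active_parameters": {
            "distance_metric": "corresponding-point mean Euclidean, flip-minimized",
            "linkage": "Ward (Lance-Williams on squared distances, lowest-index ties)",
            "resample_points": clustering.N_POINTS_DEFAULT,
            "stability_min": config.clustering.stability_min,
            "match_tolerance_ml": config.stats.match_tolerance_ml,
            "tfce": {"H": 2.0, "E": 0.5, "dh": "max/100"},
            "permutation_scheme": "Freedman-Lane",
            "sex_contrast": "women - men",
            "alpha": config.stats.alpha,
        },
    }

    # ---- cohort ----------------------------------------------------------
    try:
        spec = synthetic.CohortSpec(**{**asdict(config.cohort), "seed": int(seeds[0])})
        if isinstance(spec.age_range, list):
            spec.age_range = tuple(spec.age_range)
        cohort = synthetic.generate_cohort(spec)
    except Exception as exc:  # noqa: BLE001
        raise StageError("cohort", exc) from exc
    tract_names = list(spec.tract_baselines.keys())

    # ---- phantoms + segmentation + tract metrics -------------------------
    if config.simulate_images:
        try:
            cohort = _image_stage(config, cohort, tract_names, seeds, out, summary)
        except StageError:
            io.save_subject_table(cohort, out / "subjects.csv")
            raise
    io.save_subject_table(cohort, out / "subjects.csv")

    # ---- matching and statistics -----------------------------------------
    try:
        results = _stats_stage(config, cohort, tract_names, seeds, summary)
    except Exception as exc:  # noqa: BLE001
        raise StageError("statistics", exc) from exc

    render_report(results, out)
    summary["tables"] = {
        name: df.to_dict(orient="records") for name, df in results.items()
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return summary


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _image_stage(
    config: StudyConfig,
    cohort: pd.DataFrame,
    tract_names: List[str],
    seeds: np.ndarray,
    out: Path,
    summary: Dict,
) -> pd.DataFrame:
    """Phantoms, consensus segmentation, rasterized tract FA/volume."""
    cp = config.clustering
    centerlines = synthetic.archetype_centerlines()
    grid = _phantom_grid()
    rng_master = int(seeds[1])

    def subject_bundles(subject_index: int):
        sls, labels = [], []
        for t_i, name in enumerate(tract_names):
            geom = synthetic.BundleGeometry(
                name, centerlines[name], cp.radius, cp.n_streamlines
            )
            sls.extend(
                synthetic.generate_bundle(
                    geom, seed=(rng_master + 1000 * subject_index + t_i) % 2**31
                )
            )
            labels.extend([t_i] * cp.n_streamlines)
        return sls, np.asarray(labels)

    try:
        # pool the clustering subjects
        pooled, pooled_truth = [], []
        n_cluster = min(cp.n_cluster_subjects, len(cohort))
        for s in range(n_cluster):
            sls, labels = subject_bundles(s)
            pooled.extend(sls)
            pooled_truth.append(labels)
        pooled_truth = np.concatenate(pooled_truth)

        seg, reference_reps = clustering.consensus_cluster(
            pooled,
            k=cp.k,
            subset_size=cp.subset_size,
            n_repetitions=cp.n_repetitions,
            seed=int(seeds[2]),
            return_reference=True,
        )
        subject_col = np.repeat(
            [cohort["subject_id"].iloc[s] for s in range(n_cluster)],
            cp.n_streamlines * len(tract_names),
        )
        io.save_segmentation(seg, subject_col, out / "segmentation.csv")

        # curation stand-in: name each consensus cluster by its majority
        # ground-truth bundle
        label_sets: Dict[str, set] = {name: set() for name in tract_names}
        for lab in range(cp.k):
            members = pooled_truth[seg.labels == lab]
            if len(members) == 0:
                continue
            majority = tract_names[np.bincount(members).argmax()]
            label_sets[majority].add(lab)
        summary["tract_label_sets"] = {
            name: sorted(labs) for name, labs in label_sets.items()
        }
        with open(out / "tract_labels.json", "w") as fh:
            json.dump(
                {name: sorted(labs) for name, labs in label_sets.items()},
                fh,
                indent=2,
                sort_keys=True,
            )

        # per-subject extraction: classify each subject's streamlines against
        # the reference representatives, rasterize, and measure
        fa_cols = {name: [] for name in tract_names}
        vol_cols = {name: [] for name in tract_names}
        for s in range(len(cohort)):
            sls, _ = subject_bundles(s)
            resampled = np.stack([clustering.resample(x) for x in sls])
            labels = clustering.assign_to_clusters(resampled, reference_reps)
            # subject FA map: each tract ROI carries the subject's tract FA
            fa_map = np.zeros(grid.shape)
            rois = {}
            for name in tract_names:
                keep = [
                    i for i in range(len(sls)) if labels[i] in label_sets[name]
                ]
                if keep:
                    roi = tracts.rasterize_tract(
                        [sls[i] for i in keep], grid, name=name
                    )
                else:
                    roi = None
                rois[name] = roi
                if roi is not None:
                    fa_map[roi.mask] = cohort[f"{name}_fa"].iloc[s]
            for name in tract_names:
                roi = rois[name]
                if roi is None or not roi.mask.any():
                    fa_cols[name].append(np.nan)
                    vol_cols[name].append(np.nan)
                else:
                    fa_cols[name].append(tracts.tract_mean_fa(roi, fa_map))
                    vol_cols[name].append(tracts.tract_volume(roi))
        for name in tract_names:
            cohort[f"{name}_fa"] = fa_cols[name]
            cohort[f"{name}_vol_mm3"] = vol_cols[name]
        return cohort
    except Exception as exc:  # noqa: BLE001
        raise StageError("segmentation", exc) from exc


def _stats_stage(
    config: StudyConfig,
    cohort: pd.DataFrame,
    tract_names: List[str],
    seeds: np.ndarray,
    summary: Dict,
) -> Dict[str, pd.DataFrame]:
    sp = config.stats
    men = cohort[cohort["sex"] == "M"]
    women = cohort[cohort["sex"] == "F"]

    pairs = stats.match_by_icv(men, women, tolerance=sp.match_tolerance_ml)
    matched_men = men.set_index("subject_id").loc[[p[0] for p in pairs.pairs]]
    matched_women = women.set_index("subject_id").loc[[p[1] for p in pairs.pairs]]
    summary["icv"] = {
        "t_whole_group": stats.two_sample_t(
            men["icv_ml"].to_numpy(), women["icv_ml"].to_numpy()
        ),
        "n_matched_pairs": len(pairs),
        "t_matched": (
            stats.two_sample_t(
                matched_men["icv_ml"].to_numpy(), matched_women["icv_ml"].to_numpy()
            )
            if len(pairs) >= 2
            else None
        ),
    }
    pd.DataFrame(pairs.pairs, columns=["man_id", "woman_id"]).to_csv(
        Path(config.out_dir) / "matched_pairs.csv", index=False
    )

    design = stats.build_design(cohort, sp.terms)
    term_of = {"icv": "icv", "age": "age", "sex": "sex"}

    rows = []
    responses = []
    for name in tract_names:
        for kind in ("fa", "vol_mm3"):
            col = f"{name}_{kind}"
            if col not in cohort.columns:
                continue
            y = cohort[col].to_numpy(dtype=float)
            if np.isnan(y).any():
                continue
            if np.std(y) == 0:
                continue
            fit = stats.fit_glm(y, design)
            responses.append((name, kind, y))
            for family in sp.families:
                term = term_of[family]
                rows.append(
                    {
                        "tract": name,
                        "response": kind,
                        "family": family,
                        "beta": fit.params[term],
                        "p": fit.pvalues[term],
                        "partial_eta_sq": fit.partial_eta_sq[term],
                    }
                )
    table = pd.DataFrame(rows)
    if len(table):
        reject, adjusted = stats.bh_correct(
            table["p"].to_numpy(), alpha=sp.alpha, families=table["family"].to_numpy()
        )
        table["p_bh"] = adjusted
        table["significant"] = reject

    # per-tract sex summaries and Cohen's d (women - men)
    sex_rows = []
    for name in tract_names:
        col = f"{name}_fa"
        if col not in cohort.columns:
            continue
        wv = women[col].dropna().to_numpy()
        mv = men[col].dropna().to_numpy()
        if len(wv) < 2 or len(mv) < 2:
            continue
        sex_rows.append(
            {
                "tract": name,
                "fa_women_mean": wv.mean(),
                "fa_women_sd": wv.std(ddof=1),
                "fa_men_mean": mv.mean(),
                "fa_men_sd": mv.std(ddof=1),
                "cohen_d": stats.cohen_d(wv, mv),
            }
        )
    sex_table = pd.DataFrame(sex_rows)

    # permutation inference across tracts as units (FA response)
    fa_matrix = np.stack(
        [y for name, kind, y in responses if kind == "fa"]
    ) if any(kind == "fa" for _, kind, _ in responses) else None
    if fa_matrix is not None and len(fa_matrix) >= 1:
        perm_rows = []
        for family in sp.families:
            res = stats.permutation_inference(
                fa_matrix,
                design,
                term_of[family],
                n_perm=sp.n_perm,
                method="maxstat",
                seed=int(seeds[3]),
            )
            fa_names = [name for name, kind, _ in responses if kind == "fa"]
            for u, name in enumerate(fa_names):
                perm_rows.append(
                    {
                        "tract": name,
                        "family": family,
                        "abs_t": res.statistic[u],
                        "p_fwe": res.corrected_p[u],
                    }
                )
        perm_table = pd.DataFrame(perm_rows)
    else:
        perm_table = pd.DataFrame(columns=["tract", "family", "abs_t", "p_fwe"])

    results = {
        "effects": table,
        "sex_summaries": sex_table,
        "permutation": perm_table,
    }
    return results


def render_report(results: Dict[str, pd.DataFrame], out_dir) -> List[str]:
    """Write each results table as CSV; returns the files written.

    Empty tables produce headers-only CSVs; a missing family column is
    simply absent (with a warning), mirroring the per-family report layout.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    expected = ("effects", "sex_summaries", "permutation")
    for name in expected:
        if name not in results:
            warnings.warn(f"missing results table {name!r}; omitted", stacklevel=2)
            continue
        path = out / f"{name}.csv"
        results[name].to_csv(path, index=False)
        written.append(str(path))
    return written
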