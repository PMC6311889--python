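"""End-to-end experiment: every seed combination, fused and classified.

Enumerates the nonempty subsets of the seed list (15 for four seeds), runs
connectivity -> joint ICA fusion -> repeated-split SVM classification for
each, and reports a comparison table plus a complementarity flag: a
multi-seed combination is complementary when its mean accuracy exceeds the
best of all its proper nonempty sub-combinations.

Connectivity maps are computed once per cohort and shared across
combinations, and one split sequence is reused for every combination so that
accuracies are compared on identical partitions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ClassificationResult,
    ClassifierConfig,
    SplitScheme,
    make_splits,
    run_repeated,
)
from .cohort import CohortConfig, generate_cohort, read_cohort
from .connectivity import MapTable, SeedSpec, map_cohort
from .fusion import (
    DEFAULT_K,
    JointFeatureBuilder,
    JointICA,
    SourceGroupStats,
    rank_sources,
    split_joint_source,
)

logger = logging.getLogger("dmnfuse")


def enumerate_combinations(seed_names: Sequence[str]) -> list[tuple[str, ...]]:
    """All nonempty subsets, ordered by size then by seed position."""
    if not seed_names:
        raise ValueError("need at least one seed")
    out = []
    for size in range(1, len(seed_names) + 1):
        out.extend(itertools.combinations(seed_names, size))
    return out


def combination_label(subset: Sequence[str], seed_names: Sequence[str]) -> str:
    """Label a subset as EL<size>-<positions>, positions 1-based."""
    pos = sorted(seed_names.index(s) + 1 for s in subset)
    return f"EL{len(pos)}-{''.join(str(p) for p in pos)}"


def parse_combination_label(label: str, seed_names: Sequence[str]) -> tuple[str, ...]:
    """Inverse of :func:`combination_label` for up to 9 seeds."""
    size_s, pos_s = label[2:].split("-")
    positions = [int(ch) for ch in pos_s]
    if len(positions) != int(size_s):
        raise ValueError(f"label {label!r}: size field disagrees with positions")
    return tuple(seed_names[p - 1] for p in positions)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one full experiment."""

    cohort: CohortConfig | str = field(default_factory=CohortConfig)
    seeds: list[SeedSpec] | None = None
    k: int = DEFAULT_K
    scheme: SplitScheme = field(default_factory=SplitScheme)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    combinations: str | list[Sequence[str]] = "all"
    output_dir: str | None = None
    rng_seed: int = 0
    #: "per-split" (default, leakage-free) or "fit-once" (comparison only)
    fusion_mode: str = "per-split"

    def config_hash(self) -> str:
        return hashlib.sha256(_config_yaml(self).encode()).hexdigest()[:16]


def _config_yaml(cfg: ExperimentConfig) -> str:
    d = dataclasses.asdict(cfg)
    for key in ("C_grid", "g_grid"):
        d["classifier"][key] = [float(v) for v in d["classifier"][key]]
    if not isinstance(cfg.cohort, str):
        d["cohort"]["grid"] = list(d["cohort"]["grid"])
    if isinstance(cfg.combinations, list):
        d["combinations"] = [list(c) for c in cfg.combinations]
    return yaml.safe_dump(d, sort_keys=True)


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    cohort = d.get("cohort", {})
    if isinstance(cohort, dict):
        cohort.setdefault("grid", (20, 24, 20))
        cohort["grid"] = tuple(cohort["grid"])
        if cohort.get("seeds") is not None:
            cohort["seeds"] = [SeedSpec(**s) for s in cohort["seeds"]]
        cohort = CohortConfig(**cohort)
    seeds = d.get("seeds")
    if seeds is not None:
        seeds = [SeedSpec(**s) for s in seeds]
    combos = d.get("combinations", "all")
    if isinstance(combos, list):
        combos = [tuple(c) for c in combos]
    return ExperimentConfig(
        cohort=cohort,
        seeds=seeds,
        k=d.get("k", DEFAULT_K),
        scheme=SplitScheme(**d.get("scheme", {})),
        classifier=ClassifierConfig(**d.get("classifier", {})),
        combinations=combos,
        output_dir=d.get("output_dir"),
        rng_seed=d.get("rng_seed", 0),
        fusion_mode=d.get("fusion_mode", "per-split"),
    )


@dataclass
class ExperimentResult:
    """Per-combination results plus provenance."""

    combination_labels: list[str]
    combinations: list[tuple[str, ...]]
    classification: dict[str, ClassificationResult]
    source_stats: dict[str, SourceGroupStats]
    failures: dict[str, str]
    seed_names: list[str]
    provenance: dict

    def summary(self) -> pd.DataFrame:
        rows = []
        for lab in self.combination_labels:
            if lab in self.failures:
                rows.append({"combination": lab, "mean_accuracy": np.nan, "auc": np.nan})
                continue
            res = self.classification[lab]
            rows.append(
                {"combination": lab, "mean_accuracy": res.mean_accuracy, "auc": res.auc}
            )
        return pd.DataFrame(rows, columns=["combination", "mean_accuracy", "auc"])


def make_fusion_refit(maps: MapTable, seed_subset: Sequence[str], k: int, master_seed: int):
    """Per-split closure: fit builder + joint ICA on training subjects only.

    Each split gets its own ICA substream derived from ``master_seed`` and the
    split index, so the whole experiment flows from one master seed.
    """
    subjects = np.asarray(maps.subjects)

    def refit(train_idx: np.ndarray, test_idx: np.ndarray, split_idx: int):
        builder = JointFeatureBuilder(seed_subset=seed_subset)
        builder.fit(maps, subjects[train_idx])
        feats_tr = builder.transform(maps, subjects[train_idx])
        ica_seed = np.random.SeedSequence([master_seed, split_idx]).generate_state(1)[0]
        ica = JointICA(n_components=k, random_state=int(ica_seed % (2**31))).fit(feats_tr.X)
        feats_te = builder.transform(maps, subjects[test_idx])
        return ica.mixing_, ica.transform(feats_te.X)

    return refit


def make_fit_once_refit(maps: MapTable, seed_subset: Sequence[str], k: int, master_seed: int):
    """Comparison-only alternative to :func:`make_fusion_refit`.

    Fits the builder and decomposition on the *whole* cohort once and hands
    every split rows of that single mixing matrix.  Test subjects influence
    the decomposition and normalization, so this mode leaks information and
    is never the default; it exists to quantify that leakage against the
    per-split protocol.
    """
    builder = JointFeatureBuilder(seed_subset=seed_subset).fit(maps)
    feats = builder.transform(maps)
    ica = JointICA(n_components=k, random_state=master_seed).fit(feats.X)
    A = ica.mixing_

    def refit(train_idx: np.ndarray, test_idx: np.ndarray, split_idx: int):
        return A[train_idx], A[test_idx]

    return refit


def resolve_cohort(config: ExperimentConfig):
    """Return (scans, seeds) from either a synthetic config or a manifest."""
    if isinstance(config.cohort, str):
        scans = read_cohort(config.cohort)
        if config.seeds is None:
            raise ValueError("seeds must be given explicitly for a manifest cohort")
        return scans, config.seeds
    scans, _ = generate_cohort(config.cohort)
    seeds = config.seeds if config.seeds is not None else config.cohort.resolved_seeds()
    return scans, seeds


def run_experiment(config: ExperimentConfig, maps: MapTable | None = None) -> ExperimentResult:
    """Run the full sweep; a failed combination is logged, not fatal."""
    t0 = time.time()
    if maps is None:
        scans, seeds = resolve_cohort(config)
        maps = map_cohort(scans, seeds)  # computed once, shared by all combinations
    seed_names = list(maps.seed_names)
    if config.combinations == "all":
        combos = enumerate_combinations(seed_names)
    else:
        combos = [tuple(c) for c in config.combinations]
        for c in combos:
            if not c or not set(c) <= set(seed_names):
                raise ValueError(f"invalid combination {c!r} for seeds {seed_names}")
    labels = np.asarray(maps.groups)
    scheme = dataclasses.replace(config.scheme, rng_seed=config.rng_seed)
    splits = make_splits(labels, scheme)  # one split sequence shared across combos

    classification: dict[str, ClassificationResult] = {}
    source_stats: dict[str, SourceGroupStats] = {}
    failures: dict[str, str] = {}
    combo_labels = [combination_label(c, seed_names) for c in combos]
    if config.fusion_mode not in ("per-split", "fit-once"):
        raise ValueError(f"unknown fusion_mode {config.fusion_mode!r}")
    make_refit = (
        make_fusion_refit if config.fusion_mode == "per-split" else make_fit_once_refit
    )
    for combo, lab in zip(combos, combo_labels):
        t_combo = time.time()
        try:
            refit = make_refit(maps, combo, config.k, config.rng_seed)
            classification[lab] = run_repeated(
                labels, scheme, config.classifier, refit, splits=splits
            )
            # whole-cohort fit for the group-difference ranking of sources
            builder = JointFeatureBuilder(seed_subset=combo).fit(maps)
            feats = builder.transform(maps)
            ica = JointICA(n_components=config.k, random_state=config.rng_seed).fit(feats.X)
            source_stats[lab] = rank_sources(ica.mixing_, labels)
            logger.info(
                "combination %s: mean accuracy %.3f, AUC %.3f (%.1fs)",
                lab,
                classification[lab].mean_accuracy,
                classification[lab].auc,
                time.time() - t_combo,
            )
        except Exception as exc:
            failures[lab] = str(exc)
            logger.warning("combination %s failed: %s", lab, exc)

    result = ExperimentResult(
        combination_labels=combo_labels,
        combinations=[tuple(c) for c in combos],
        classification=classification,
        source_stats=source_stats,
        failures=failures,
        seed_names=seed_names,
        provenance={
            "config_hash": config.config_hash(),
            "version": __version__,
            "rng_seed": config.rng_seed,
            "runtime_s": round(time.time() - t0, 3),
        },
    )
    if config.output_dir is not None:
        write_result(result, config.output_dir, config)
    return result


def complementarity_report(result: ExperimentResult) -> pd.DataFrame:
    """Flag multi-seed combinations beating every proper sub-combination."""
    acc = {
        lab: result.classification[lab].mean_accuracy
        for lab in result.combination_labels
        if lab not in result.failures
    }
    rows = []
    for combo, lab in zip(result.combinations, result.combination_labels):
        if len(combo) < 2 or lab not in acc:
            continue
        subs = []
        for size in range(1, len(combo)):
            for sub in itertools.combinations(combo, size):
                sub_lab = combination_label(sub, result.seed_names)
                if sub_lab not in acc:
                    raise ValueError(
                        f"sub-combination {sub_lab} of {lab} missing from the result"
                    )
                subs.append(acc[sub_lab])
        rows.append(
            {
                "combination": lab,
                "mean_accuracy": acc[lab],
                "best_sub_accuracy": max(subs),
                "complementary": acc[lab] > max(subs),
            }
        )
    return pd.DataFrame(
        rows, columns=["combination", "mean_accuracy", "best_sub_accuracy", "complementary"]
    )


def write_result(result: ExperimentResult, output_dir: str | Path, config: ExperimentConfig | None = None) -> None:
    """Write summary, per-split, ROC and provenance tables as CSV/YAML."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary().to_csv(out / "summary.csv", index=False, float_format="%.6f")
    rows = []
    for lab in result.combination_labels:
        if lab in result.failures:
            continue
        res = result.classification[lab]
        for i, a in enumerate(res.per_split_accuracy):
            c, g = res.chosen_hyperparams[i]
            rows.append({"split": i, "combination": lab, "C": c, "g": g, "accuracy": a})
    pd.DataFrame(rows, columns=["split", "combination", "C", "g", "accuracy"]).to_csv(
        out / "per_split.csv", index=False, float_format="%.6f"
    )
    roc_rows = []
    for lab in result.combination_labels:
        if lab in result.failures:
            continue
        for fpr, tpr in result.classification[lab].roc_points:
            roc_rows.append({"combination": lab, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(roc_rows, columns=["combination", "fpr", "tpr"]).to_csv(
        out / "roc_points.csv", index=False, float_format="%.6f"
    )
    try:
        complementarity_report(result).to_csv(
            out / "complementarity.csv", index=False, float_format="%.6f"
        )
    except ValueError:
        pass  # sub-combinations absent: skip the report file
    prov = dict(result.provenance)
    if result.failures:
        prov["failures"] = dict(result.failures)
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)


def k_sweep(
    maps: MapTable,
    seed_subset: Sequence[str],
    k_values: Sequence[int] = (6, 8, 10, 12, 14, 16),
    k_ref: int = DEFAULT_K,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Refit at each K and report stability of the most-different source.

    For each K the whole-cohort decomposition is refitted, the source whose
    mixing column differs most between groups is found, and its joint map is
    correlated (absolute Pearson) with the reference-K map.
    """
    labels = np.asarray(maps.groups)
    builder = JointFeatureBuilder(seed_subset=seed_subset).fit(maps)
    feats = builder.transform(maps)

    def top_map(k):
        ica = JointICA(n_components=k, random_state=rng_seed).fit(feats.X)
        stats = rank_sources(ica.mixing_, labels)
        return ica.components_[stats.most_different], stats
    ref_map, _ = top_map(k_ref)
    rows = []
    for k in k_values:
        m, stats = top_map(k)
        r = np.corrcoef(m, ref_map)[0, 1]
        rows.append(
            {
                "k": k,
                "most_different_source": stats.most_different,
                "abs_corr_with_reference": abs(float(r)),
            }
        )
    return pd.DataFrame(rows, columns=["k", "most_different_source", "abs_corr_with_reference"])
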