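"""End-to-end orchestration: score -> group -> select -> train -> evaluate.

``run_typicality`` chains vocabulary building, binary encoding, the Hamming
distance matrix, MDS embedding and KDE typicality scoring for a case table.
``run_experiment1`` / ``run_experiment2`` reproduce the two instance-selection
protocols on a (typically synthetic) fixture with slide images:

* Experiment I trains one classifier per fold on a typicality-balanced pool
  and compares test accuracy on the typical vs the atypical group.
* Experiment II compares training-set compositions (typical:intermediate:
  atypical ratios) on a common stratified K-fold, against the keep-everything
  baseline (3:3:3).

Metrics are pooled by summing fold confusion matrices, so with a partitioning
protocol every case is tested exactly once per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embedding import HammingMDS
from .ihc import CaseRecord, StainPatternEncoder, distance_matrix
from .mil import (
    AttentionMILClassifier,
    MILConfig,
    aggregate_slide,
    evaluate_model,
    extract_patches,
    make_bags,
)
from .selection import (
    FoldPlan,
    TypicalityGrouping,
    group_by_typicality,
    plan_experiment1,
    plan_experiment2,
)
from .synthetic import IHCGeneratorConfig, SlideGeneratorConfig, gen_dataset
from .typicality import TypicalityScorer

logger = logging.getLogger(__name__)

__all__ = [
    "TypicalityResult",
    "run_typicality",
    "experiment_fixture",
    "run_experiment1",
    "run_experiment2",
]


@dataclass
class TypicalityResult:
    case_ids: list[str]
    subtypes: np.ndarray
    coords: np.ndarray
    typicality: np.ndarray  # (N, K)
    own_typicality: np.ndarray
    bandwidth: float
    stress: float
    vocabulary: tuple[str, ...]
    grouping: TypicalityGrouping = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        K = self.typicality.shape[1]
        df = pd.DataFrame(
            {
                "case_id": self.case_ids,
                "subtype": self.subtypes,
                **{f"t_{k}": self.typicality[:, k] for k in range(K)},
                "own_typicality": self.own_typicality,
            }
        )
        if self.grouping is not None:
            df["group"] = [self.grouping.group[c] for c in self.case_ids]
        return df


def run_typicality(
    cases: list[CaseRecord],
    min_usage: int = 10,
    n_components: int = 3,
    bandwidth: str = "spread",
    seed: int = 0,
) -> TypicalityResult:
    """Full typicality chain on a case list, including the three-way grouping."""
    enc = StainPatternEncoder(min_usage=min_usage).fit(cases)
    patterns = enc.transform(cases)
    for c, p in zip(cases, patterns):
        c.pattern = p
        if p.sum() == 0:
            logger.warning("case %s has an all-zero filtered pattern (retained)", c.case_id)
    D = distance_matrix(patterns)
    mds = HammingMDS(n_components=n_components, random_state=seed)
    coords = mds.fit_transform(D)
    labels = np.array([c.subtype for c in cases])
    scorer = TypicalityScorer(bandwidth=bandwidth).fit(coords, labels)
    T = scorer.transform()
    own = scorer.own_typicality()
    ids = [c.case_id for c in cases]
    grouping = group_by_typicality(ids, labels, own)
    return TypicalityResult(
        case_ids=ids,
        subtypes=labels,
        coords=coords,
        typicality=T,
        own_typicality=own,
        bandwidth=scorer.bandwidth_,
        stress=mds.stress_,
        vocabulary=enc.vocabulary_.names,
        grouping=grouping,
    )


def experiment_fixture(
    seed: int = 0,
    n_per_subtype: int = 15,
    image_size: int = 256,
    atypicality_rate: float = 0.3,
    atypical_mixing: float | None = None,
) -> dict:
    """Desk-scale coherent fixture for the selection experiments.

    Same generator family as the full-size defaults, scaled to
    ``n_per_subtype`` cases per subtype and ``image_size`` px slides so a
    five-fold experiment runs in minutes on one core.
    """
    ihc_cfg = IHCGeneratorConfig(
        cases_per_subtype=(n_per_subtype,) * 3,
        atypicality_rate=atypicality_rate,
        seed=seed,
    )
    slide_kw = {} if atypical_mixing is None else {"atypical_mixing": atypical_mixing}
    slide_cfg = SlideGeneratorConfig(image_size=image_size, seed=seed + 1, **slide_kw)
    return gen_dataset(ihc_cfg, slide_cfg)


def _slides_for(data: dict, ids: list[str], split: str) -> dict:
    return {
        cid: {**data["slides"][cid], "split": split}
        for cid in ids
    }


def _train_fold(data: dict, fold, cfg: MILConfig, seed: int) -> AttentionMILClassifier:
    slides = {**_slides_for(data, fold.train, "train"), **_slides_for(data, fold.validation, "validation")}
    # tissue masks: synthetic slides carry the planted mask only for scoring;
    # training detects tissue from the image itself
    for d in slides.values():
        d.pop("mask", None)
    clf = AttentionMILClassifier(config=cfg, random_state=seed)
    clf.fit(slides)
    return clf


def _predict_ids(clf: AttentionMILClassifier, data: dict, ids: list[str], seed: int) -> np.ndarray:
    slides = {cid: data["slides"][cid] for cid in ids}
    return clf.predict(slides, seed=seed)


def attention_localization(
    clf: AttentionMILClassifier, data: dict, cid: str, seed: int = 0
) -> tuple[float, float]:
    """Mean attention weight on planted-foreground vs background patches."""
    cfg = clf._cfg
    d = data["slides"][cid]
    from .mil import detect_tissue

    mask = detect_tissue(d["image"])
    patches = extract_patches(
        d["image"], mask, cfg.patch_size, cfg.max_patches, cfg.min_tissue_fraction,
        seed=seed, slide_id=cid,
    )
    bags = make_bags(patches, cfg.n_bags, min(cfg.bag_size, len(patches)), seed=seed + 1)
    fg = d["fg_mask"]
    P = cfg.patch_size
    w_in, w_out = [], []
    for bag in bags:
        _, a = clf.predict_bag(bag)
        for wi, patch in zip(a, bag.patches):
            r, c = patch.location
            frac = fg[r : r + P, c : c + P].mean()
            (w_in if frac >= 0.5 else w_out).append(wi)
    mean_in = float(np.mean(w_in)) if w_in else np.nan
    mean_out = float(np.mean(w_out)) if w_out else np.nan
    return mean_in, mean_out


def _default_mil_config() -> MILConfig:
    return MILConfig.tiny(n_bags=4, bag_size=16, n_epochs=10, learning_rate=3e-3)


def run_experiment1(
    data: dict,
    seed: int = 0,
    n_folds: int = 5,
    mil_config: MILConfig | None = None,
    min_usage: int = 3,
    with_attention: bool = True,
) -> dict:
    """Experiment I: typicality-selected testing with a shared training pool.

    Trains one model per fold and evaluates it on both the typical and the
    atypical test subgroups (their training pools are identical by
    construction).  Returns pooled accuracy/macro-F1/confusion per target
    group and, optionally, attention-localization statistics on correctly
    classified typical test slides.
    """
    cfg = mil_config or _default_mil_config()
    res = run_typicality(data["cases"], min_usage=min_usage, seed=seed)
    plans = {
        g: plan_experiment1(res.grouping, g, n_folds=n_folds, seed=seed)
        for g in ("typical", "atypical")
    }
    label_of = {c.case_id: c.subtype for c in data["cases"]}
    preds: dict[str, dict[str, int]] = {g: {} for g in plans}
    attention_hits = []
    for f in range(n_folds):
        clf = _train_fold(data, plans["typical"].folds[f], cfg, seed + 10 * f)
        for g, plan in plans.items():
            test_ids = plan.folds[f].test
            yp = _predict_ids(clf, data, test_ids, seed + 500 + f)
            for cid, p in zip(test_ids, yp):
                preds[g][cid] = int(p)
        if with_attention:
            for cid in plans["typical"].folds[f].test:
                if preds["typical"][cid] == label_of[cid]:
                    m_in, m_out = attention_localization(clf, data, cid, seed=seed + 900 + f)
                    if np.isfinite(m_in) and np.isfinite(m_out):
                        attention_hits.append(m_in > m_out)
    out = {"seed": seed, "bandwidth": res.bandwidth}
    for g in plans:
        ids = sorted(preds[g])
        acc, f1, cm = evaluate_model(
            [label_of[c] for c in ids], [preds[g][c] for c in ids], cfg.n_classes
        )
        out[g] = {"accuracy": acc, "macro_f1": f1, "confusion": cm.tolist(), "n_test": len(ids)}
    if with_attention:
        out["attention_localized_fraction"] = (
            float(np.mean(attention_hits)) if attention_hits else np.nan
        )
        out["n_attention_slides"] = len(attention_hits)
    return out


def run_experiment2(
    data: dict,
    ratios: list[tuple[int, int, int]] = [(3, 3, 3), (3, 2, 1), (1, 2, 3)],
    seed: int = 0,
    n_folds: int = 5,
    mil_config: MILConfig | None = None,
    min_usage: int = 3,
) -> dict:
    """Experiment II: typicality-ratio-selected training over a common K-fold.

    For each ratio, trains per fold on the selected pool and tests on the
    fold's held-out cases; every case is tested exactly once per ratio.
    """
    cfg = mil_config or _default_mil_config()
    res = run_typicality(data["cases"], min_usage=min_usage, seed=seed)
    label_of = {c.case_id: c.subtype for c in data["cases"]}
    out = {"seed": seed, "bandwidth": res.bandwidth, "ratios": {}}
    for ratio in ratios:
        plan = plan_experiment2(res.grouping, ratio, n_folds=n_folds, seed=seed)
        y_true, y_pred = [], []
        n_train_total = 0
        for f, fold in enumerate(plan.folds):
            clf = _train_fold(data, fold, cfg, seed + 10 * f)
            yp = _predict_ids(clf, data, fold.test, seed + 500 + f)
            y_true.extend(label_of[c] for c in fold.test)
            y_pred.extend(int(p) for p in yp)
            n_train_total += len(fold.train) + len(fold.validation)
        acc, f1, cm = evaluate_model(y_true, y_pred, cfg.n_classes)
        out["ratios"]["{}:{}:{}".format(*ratio)] = {
            "accuracy": acc,
            "macro_f1": f1,
            "confusion": cm.tolist(),
            "mean_train_size": n_train_total / n_folds,
        }
    return out
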