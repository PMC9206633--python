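"""Typicality-based instance selection: grouping and cross-validation fold plans.

Within each subtype, cases are ranked by own-subtype typicality and split into
three contiguous groups of near-equal size — typical (top third),
intermediate, atypical (bottom third).  Two selection protocols are built on
the grouping:

* **Experiment I** (selection of the *testing* data): every subtype x group
  cell is split into ``n_folds`` random subgroups; fold ``f`` tests on
  subgroup ``f`` of the target group (typical or atypical) while training on
  everything outside subgroup ``f`` of every group — so the training pool is
  identical whichever group is being tested.
* **Experiment II** (selection of the *training* data): a plain stratified
  K-fold over all cases; from each fold's training pool a ratio
  ``(r_t, r_i, r_a)`` with entries in {1, 2, 3} keeps ``r_g/3`` of each
  typicality group.  Ratio ``(3, 3, 3)`` keeps everything and is the
  baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GROUPS",
    "TypicalityGrouping",
    "Fold",
    "FoldPlan",
    "group_by_typicality",
    "plan_experiment1",
    "plan_experiment2",
    "select_by_ratio",
    "split_train_validation",
]

GROUPS = ("typical", "intermediate", "atypical")


@dataclass
class TypicalityGrouping:
    """Per-case typicality group and per-subtype descending-typicality order."""

    group: dict[str, str]  # case_id -> group name
    order: dict[int, list[str]]  # subtype -> case_ids, descending typicality
    subtype: dict[str, int]  # case_id -> subtype

    def members(self, subtype: int, group: str) -> list[str]:
        return [c for c in self.order[subtype] if self.group[c] == group]


@dataclass
class Fold:
    train: list[str]
    validation: list[str]
    test: list[str]


@dataclass
class FoldPlan:
    protocol: str  # "experiment1" | "experiment2" | "baseline"
    n_folds: int
    folds: list[Fold]
    seed: int
    ratio: tuple[int, int, int] | None = None
    target_group: str | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = {
            "protocol": self.protocol,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "ratio": list(self.ratio) if self.ratio else None,
            "target_group": self.target_group,
            "folds": [
                {"train": f.train, "validation": f.validation, "test": f.test}
                for f in self.folds
            ],
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            protocol=d["protocol"],
            n_folds=d["n_folds"],
            seed=d["seed"],
            ratio=tuple(d["ratio"]) if d["ratio"] else None,
            target_group=d["target_group"],
            folds=[Fold(f["train"], f["validation"], f["test"]) for f in d["folds"]],
            meta=d.get("meta", {}),
        )


def _third_sizes(n: int) -> tuple[int, int, int]:
    """Split n into three near-equal parts, extras assigned typical-first."""
    base, extra = divmod(n, 3)
    return tuple(base + (1 if i < extra else 0) for i in range(3))


def group_by_typicality(
    case_ids: Sequence[str], subtypes: Sequence[int], own_typicality: Sequence[float]
) -> TypicalityGrouping:
    """Split each subtype's cases into typical/intermediate/atypical thirds.

    Cases are sorted per subtype by descending own-subtype typicality (ties
    broken by case_id); the top third is typical, with size remainders
    assigned typical-first so group sizes differ by at most one.
    """
    case_ids = list(case_ids)
    subtypes = np.asarray(subtypes)
    own = np.asarray(own_typicality, dtype=float)
    group: dict[str, str] = {}
    order: dict[int, list[str]] = {}
    sub_of = dict(zip(case_ids, (int(s) for s in subtypes)))
    for k in np.unique(subtypes):
        idx = [i for i in range(len(case_ids)) if subtypes[i] == k]
        if len(idx) < 3:
            raise ValueError(f"subtype {k} has {len(idx)} cases; need >= 3 to form groups")
        idx.sort(key=lambda i: (-own[i], case_ids[i]))
        ordered = [case_ids[i] for i in idx]
        order[int(k)] = ordered
        nt, ni, na = _third_sizes(len(ordered))
        for c in ordered[:nt]:
            group[c] = "typical"
        for c in ordered[nt : nt + ni]:
            group[c] = "intermediate"
        for c in ordered[nt + ni :]:
            group[c] = "atypical"
    return TypicalityGrouping(group=group, order=order, subtype=sub_of)


def _split_into_subgroups(ids: list[str], n_folds: int, rng: np.random.Generator) -> list[list[str]]:
    ids = list(ids)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    return [shuffled[f::n_folds] for f in range(n_folds)]


def plan_experiment1(
    grouping: TypicalityGrouping,
    target_group: str,
    n_folds: int = 5,
    seed: int = 0,
    validation_fraction: float = 0.25,
) -> FoldPlan:
    """Typicality-selected *testing*: fold f tests subgroup f of the target group.

    Subgroup splits depend only on ``seed``, so the training pool of fold f is
    identical across target groups — the classifier trained once per fold can
    be evaluated on both the typical and the atypical test sets.
    """
    if target_group not in ("typical", "atypical"):
        raise ValueError("target_group must be 'typical' or 'atypical'")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    # deterministic subgroup split per subtype x group cell, independent of target
    subgroups: dict[tuple[int, str], list[list[str]]] = {}
    for k in sorted(grouping.order):
        for g in GROUPS:
            members = grouping.members(k, g)
            if len(members) < n_folds:
                raise ValueError(
                    f"subtype {k} group '{g}' has {len(members)} cases < n_folds={n_folds}"
                )
            subgroups[(k, g)] = _split_into_subgroups(members, n_folds, rng)
    folds = []
    for f in range(n_folds):
        test = sorted(
            c for k in sorted(grouping.order) for c in subgroups[(k, target_group)][f]
        )
        pool = sorted(
            c
            for (k, g), sgs in subgroups.items()
            for fi, sg in enumerate(sgs)
            if fi != f
            for c in sg
        )
        train, val = split_train_validation(
            pool, [grouping.subtype[c] for c in pool], 1 - validation_fraction, seed + 1000 + f
        )
        folds.append(Fold(train=train, validation=val, test=test))
    return FoldPlan(
        protocol="experiment1", n_folds=n_folds, folds=folds, seed=seed, target_group=target_group
    )


def _keep_counts(pool_by_sub: dict[int, list[str]], r: int) -> dict[int, int]:
    """Per-subtype keep counts for one typicality group at ratio component r.

    The group-level target is round-half-up(r/3 * group size); it is allocated
    across subtypes by largest remainder so the total is exact and every
    nonempty cell keeps at least one case.
    """
    total = sum(len(v) for v in pool_by_sub.values())
    if total == 0:
        return {k: 0 for k in pool_by_sub}
    target = int(np.floor(r / 3 * total + 0.5))
    target = max(target, sum(1 for v in pool_by_sub.values() if v))
    quotas = {k: r / 3 * len(v) for k, v in pool_by_sub.items()}
    keep = {k: min(int(np.floor(q)), len(pool_by_sub[k])) for k, q in quotas.items()}
    for k, v in pool_by_sub.items():
        if v and keep[k] == 0:
            keep[k] = 1
    rem = target - sum(keep.values())
    by_frac = sorted(pool_by_sub, key=lambda k: (-(quotas[k] - np.floor(quotas[k])), k))
    i = 0
    while rem > 0 and i < 10 * len(by_frac):
        k = by_frac[i % len(by_frac)]
        if keep[k] < len(pool_by_sub[k]):
            keep[k] += 1
            rem -= 1
        i += 1
    return keep


def select_by_ratio(
    pool: Sequence[str],
    grouping: TypicalityGrouping,
    ratio: tuple[int, int, int],
    rng: np.random.Generator,
) -> list[str]:
    """Keep ``r_g/3`` of each typicality group from a training pool.

    The group-level keep count is round-half-up(r_g/3 x group pool size);
    a ratio entry of 3 keeps the group in full.
    """
    kept: list[str] = []
    subtypes = sorted(grouping.order)
    for g, r in zip(GROUPS, ratio):
        pool_by_sub = {
            k: [c for c in pool if grouping.subtype[c] == k and grouping.group[c] == g]
            for k in subtypes
        }
        if r == 3:
            kept.extend(c for v in pool_by_sub.values() for c in v)
            continue
        counts = _keep_counts(pool_by_sub, r)
        for k, cell in pool_by_sub.items():
            take = counts[k]
            if take >= len(cell):
                kept.extend(cell)
            else:
                sel = rng.choice(len(cell), size=take, replace=False)
                kept.extend(cell[i] for i in sorted(sel))
    return sorted(kept)


def plan_experiment2(
    grouping: TypicalityGrouping,
    ratio: tuple[int, int, int] = (3, 3, 3),
    n_folds: int = 5,
    seed: int = 0,
    validation_fraction: float = 0.25,
) -> FoldPlan:
    """Typicality-ratio-selected *training* over a stratified K-fold.

    ``ratio = (r_typical, r_intermediate, r_atypical)`` with entries in
    {1, 2, 3}: keep ``r_g/3`` of each group from the fold's training pool,
    sampled uniformly.  ``(3, 3, 3)`` is the no-selection baseline.
    """
    ratio = tuple(int(r) for r in ratio)
    if len(ratio) != 3 or any(r not in (1, 2, 3) for r in ratio):
        raise ValueError("ratio must be a triple with entries in {1, 2, 3}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    # stratified-by-subtype random K-fold over all cases
    fold_of: dict[str, int] = {}
    for k in sorted(grouping.order):
        ids = sorted(grouping.order[k])
        for f, sg in enumerate(_split_into_subgroups(ids, n_folds, rng)):
            for c in sg:
                fold_of[c] = f
    all_ids = sorted(fold_of)
    folds = []
    for f in range(n_folds):
        test = sorted(c for c in all_ids if fold_of[c] == f)
        pool = [c for c in all_ids if fold_of[c] != f]
        kept = select_by_ratio(pool, grouping, ratio, rng)
        train, val = split_train_validation(
            kept, [grouping.subtype[c] for c in kept], 1 - validation_fraction, seed + 2000 + f
        )
        folds.append(Fold(train=train, validation=val, test=test))
    protocol = "baseline" if ratio == (3, 3, 3) else "experiment2"
    return FoldPlan(protocol=protocol, n_folds=n_folds, folds=folds, seed=seed, ratio=ratio)


def split_train_validation(
    ids: Sequence[str], subtypes: Sequence[int], fraction: float = 0.75, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified train/validation split (default 75%/25%).

    At least one validation case is kept per subtype; deterministic given
    ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be strictly between 0 and 1")
    ids = list(ids)
    subtypes = list(subtypes)
    if len(ids) < 4:
        raise ValueError("need at least 4 cases to split")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    for k in sorted(set(subtypes)):
        members = sorted(ids[i] for i in range(len(ids)) if subtypes[i] == k)
        if len(members) < 2:
            raise ValueError(f"subtype {k} has too few cases to keep a validation case")
        n_val = max(1, int(np.floor(len(members) * (1 - fraction) + 0.5)))
        n_val = min(n_val, len(members) - 1)
        perm = rng.permutation(len(members))
        val.extend(members[i] for i in perm[:n_val])
        train.extend(members[i] for i in perm[n_val:])
    return sorted(train), sorted(val)
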