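"""Train/validation layout families for blocked splitting along reporters.

Five families are provided:

* ``zebra`` — alternating fixed-length training blocks and validation
  spacers, the layout used when training data is sliced evenly along each
  reporter (spacer = round(block * (1-f)/f), which makes the 25/75 ratio
  exact for 16-bp blocks at f = 0.25);
* ``single_block`` — one contiguous training block per reporter at a chosen
  shift from the 5' end;
* ``random_blocks`` — k = round(f*L/b) non-overlapping blocks of length b
  placed uniformly at random;
* ``reporter_holdout`` — all SNVs of a target reporter go to validation,
  other reporters contribute training per the zebra base layout, or entirely
  when ``use_complete_training`` is set;
* ``grouped_holdout`` — as reporter_holdout, but every other reporter sharing
  the target's sequence (a duplicated reporter assayed in another cell type)
  is excluded from training as well.

Labels are defined on reporter *positions* and lifted to SNVs, so the three
alternative alleles at one position can never straddle the split.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRAIN, VALIDATION, EXCLUDED = 0, 1, 2
LABEL_NAMES = {TRAIN: "train", VALIDATION: "validation", EXCLUDED: "excluded"}


class LayoutError(ValueError):
    pass


class SplitFamily(str, enum.Enum):
    ZEBRA = "zebra"
    SINGLE_BLOCK = "single_block"
    RANDOM_BLOCKS = "random_blocks"
    REPORTER_HOLDOUT = "reporter_holdout"
    GROUPED_HOLDOUT = "grouped_holdout"


@dataclass
class SplitConfig:
    family: SplitFamily = SplitFamily.ZEBRA
    block_length: int = 16
    train_fraction: float = 0.25
    shift_fraction: float = 0.0
    target_reporter_id: str | None = None
    use_complete_training: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.family = SplitFamily(self.family)
        if self.block_length < 1:
            raise LayoutError("block_length must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise LayoutError("train_fraction must lie in (0, 1)")
        if self.shift_fraction < 0 or self.shift_fraction + self.train_fraction > 1:
            raise LayoutError("shift_fraction + train_fraction must be <= 1")


@dataclass
class SplitLayout:
    """Per-SNV train/validation/excluded assignment.

    ``labels`` is aligned with ``snv_ids``; ``position_labels`` keeps the
    underlying per-position assignment per reporter for auditing.
    """

    snv_ids: list[str]
    labels: np.ndarray
    position_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != len(self.snv_ids):
            raise LayoutError("labels and snv_ids lengths differ")

    @property
    def train_mask(self) -> np.ndarray:
        return self.labels == TRAIN

    @property
    def validation_mask(self) -> np.ndarray:
        return self.labels == VALIDATION

    @property
    def per_reporter_train_fraction(self) -> dict[str, float]:
        out = {}
        for rid, pl in self.position_labels.items():
            out[rid] = float(np.mean(pl == TRAIN))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid, pl in self.position_labels.items():
            for pos, lab in enumerate(pl):
                rows.append((rid, pos, LABEL_NAMES[int(lab)]))
        return pd.DataFrame(rows, columns=["reporter_id", "position", "label"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# position-level splitters (return boolean train masks over positions)


def zebra_split(reporter_length: int, block_length: int,
                train_fraction: float) -> np.ndarray:
    """Alternating training blocks and validation spacers, phase 0.

    The spacer is ``round(block * (1 - f) / f)``; the trailing partial period
    is assigned entirely to validation.
    """
    f = train_fraction
    if block_length > reporter_length * f:
        raise LayoutError(
            f"block_length {block_length} exceeds reporter_length * "
            f"train_fraction = {reporter_length * f:.1f}"
        )
    spacer = int(np.round(block_length * (1.0 - f) / f))
    period = block_length + spacer
    positions = np.arange(reporter_length)
    n_full = reporter_length // period
    return (positions // period < n_full) & (positions % period < block_length)


def single_block_split(reporter_length: int, train_fraction: float,
                       shift_fraction: float) -> np.ndarray:
    """One contiguous training block; endpoints use round-half-even."""
    if shift_fraction < 0 or shift_fraction + train_fraction > 1:
        raise LayoutError("shift_fraction + train_fraction must be <= 1")
    start = int(np.round(shift_fraction * reporter_length))
    length = int(np.round(train_fraction * reporter_length))
    end = min(start + length, reporter_length)
    mask = np.zeros(reporter_length, dtype=bool)
    mask[start:end] = True
    return mask


def random_blocks_split(reporter_length: int, block_length: int,
                        train_fraction: float,
                        rng: np.random.Generator) -> np.ndarray:
    """k = round(f*L/b) non-overlapping blocks, uniform over all placements.

    Uses the gap bijection: choosing k of L - k*b + k slots and spreading
    them by (b - 1) yields every non-overlapping placement with equal
    probability, so no rejection sampling is needed.
    """
    L, b, f = reporter_length, block_length, train_fraction
    k = int(np.round(f * L / b))
    if k < 1:
        raise LayoutError("train fraction too small to fit one block")
    if k * b > L:
        raise LayoutError(f"{k} blocks of {b} bp cannot fit in {L} bp")
    slots = L - k * b + k
    chosen = np.sort(rng.choice(slots, size=k, replace=False))
    starts = chosen + np.arange(k) * (b - 1)
    mask = np.zeros(L, dtype=bool)
    for s in starts:
        mask[s : s + b] = True
    return mask


# ---------------------------------------------------------------------------
# dataset-level layout construction


def _position_mask_for(family: SplitFamily, length: int, cfg: SplitConfig,
                       rng: np.random.Generator) -> np.ndarray:
    if family == SplitFamily.ZEBRA:
        return zebra_split(length, cfg.block_length, cfg.train_fraction)
    if family == SplitFamily.SINGLE_BLOCK:
        return single_block_split(length, cfg.train_fraction, cfg.shift_fraction)
    if family == SplitFamily.RANDOM_BLOCKS:
        return random_blocks_split(length, cfg.block_length, cfg.train_fraction, rng)
    raise LayoutError(f"{family} is not a position-level family")


def build_layout(dataset, config: SplitConfig) -> SplitLayout:
    """Lift a split family to a per-SNV assignment over a dataset.

    ``dataset`` needs ``reporters`` (with ``reporter_id``, ``length``,
    ``sequence``) and ``snvs`` (with ``reporter_id``, ``position``) — the
    synthetic dataset and the file-backed dataset both qualify.
    """
    reporters = list(dataset.reporters)
    by_id = {r.reporter_id: r for r in reporters}
    fam = config.family

    if fam in (SplitFamily.REPORTER_HOLDOUT, SplitFamily.GROUPED_HOLDOUT):
        target = config.target_reporter_id
        if target is None or target not in by_id:
            raise LayoutError(f"unknown target reporter {target!r}")

    position_labels: dict[str, np.ndarray] = {}
    for idx, rep in enumerate(reporters):
        rng = np.random.default_rng([int(config.seed), idx])
        if fam in (SplitFamily.ZEBRA, SplitFamily.SINGLE_BLOCK,
                   SplitFamily.RANDOM_BLOCKS):
            mask = _position_mask_for(fam, rep.length, config, rng)
            labels = np.where(mask, TRAIN, VALIDATION).astype(np.int8)
        else:
            target = by_id[config.target_reporter_id]
            if rep.reporter_id == target.reporter_id:
                labels = np.full(rep.length, VALIDATION, dtype=np.int8)
            elif (fam == SplitFamily.GROUPED_HOLDOUT
                  and rep.sequence == target.sequence):
                labels = np.full(rep.length, EXCLUDED, dtype=np.int8)
            elif config.use_complete_training:
                labels = np.full(rep.length, TRAIN, dtype=np.int8)
            else:
                mask = zebra_split(rep.length, config.block_length,
                                   config.train_fraction)
                labels = np.where(mask, TRAIN, VALIDATION).astype(np.int8)
        position_labels[rep.reporter_id] = labels

    snv_ids = []
    snv_labels = []
    for snv in dataset.snvs:
        snv_ids.append(snv.snv_id)
        snv_labels.append(position_labels[snv.reporter_id][snv.position])
    return SplitLayout(snv_ids=snv_ids, labels=np.array(snv_labels, dtype=np.int8),
                       position_labels=position_labels)


# ---------------------------------------------------------------------------
# audit


def audit_layout(layout: SplitLayout, dataset) -> dict:
    """Consistency report: per-reporter train fractions, training-block
    length histogram, and invariant violations (empty list when clean)."""
    violations: list[str] = []
    n = len(layout.snv_ids)
    if len(set(layout.snv_ids)) != n:
        violations.append("duplicate SNV assignments")
    counts = {
        "train": int(np.sum(layout.labels == TRAIN)),
        "validation": int(np.sum(layout.labels == VALIDATION)),
        "excluded": int(np.sum(layout.labels == EXCLUDED)),
    }
    if sum(counts.values()) != n:
        violations.append("labels do not partition the SNV set")

    # position atomicity: all alleles at one position share a label
    per_pos: dict[tuple[str, int], set[int]] = {}
    for snv, lab in zip(dataset.snvs, layout.labels):
        per_pos.setdefault((snv.reporter_id, snv.position), set()).add(int(lab))
    for key, labs in per_pos.items():
        if len(labs) > 1:
            violations.append(f"position {key} straddles labels {sorted(labs)}")

    block_hist: dict[int, int] = {}
    for pl in layout.position_labels.values():
        run = 0
        for lab in np.append(pl, -1):  # sentinel flushes the last run
            if lab == TRAIN:
                run += 1
            elif run:
                block_hist[run] = block_hist.get(run, 0) + 1
                run = 0
    return {
        "per_reporter_train_fraction": layout.per_reporter_train_fraction,
        "label_counts": counts,
        "train_block_length_histogram": dict(sorted(block_hist.items())),
        "violations": violations,
    }
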