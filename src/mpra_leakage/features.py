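"""Feature providers: motif-impact, genomic-track, and alien features.

Motif features follow the binding-model route: for every SNV, the P-value of
the best motif occurrence overlapping the substituted base (reference
allele), and the P-value fold change after substituting the alternative
allele.  Score-to-P-value conversion uses an exact dynamic program over the
background word distribution on a discretised score grid, the standard
construction behind precomputed threshold-to-P-value dictionaries.

Track features are per-reporter min-max-scaled per-base signal values plus a
per-reporter constant column holding the unscaled track mean.  Alien features
apply the same processing to values looked up at unrelated coordinates
(``(reporter_start + position) mod alien_region_length``): locally
autocorrelated, biologically meaningless — the negative control for
train/validation leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DNA_INDEX, PWM, PWMOrder, SignalTrack

logger = logging.getLogger(__name__)

PVALUE_GRID_BINS = 1000  # default resolution: score range / 1000


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# P-value tables


@dataclass
class PvalueTable:
    """Exact tail distribution of a PWM score on a discretised grid.

    Weights are rounded once to integer multiples of ``resolution``; scoring
    and the dynamic program both use the rounded matrix, so a table lookup for
    any scored word is exact for the rounded matrix and within one grid bin
    per position of the float-weight score.
    """

    motif_id: str
    order: PWMOrder
    resolution: float
    int_weights: np.ndarray  # steps x alphabet, int64
    min_score: int  # smallest achievable integer score
    sf: np.ndarray  # sf[i] = P(score_int >= min_score + i)

    @property
    def thresholds(self) -> np.ndarray:
        """Score grid, descending (matching non-increasing tail P-values)."""
        return (self.min_score + np.arange(len(self.sf))[::-1]) * self.resolution

    @property
    def pvalues(self) -> np.ndarray:
        return self.sf[::-1]

    def score_int(self, word: np.ndarray) -> int:
        iw = self.int_weights
        if self.order == PWMOrder.MONO:
            return int(iw[np.arange(len(word)), word].sum())
        steps = np.arange(len(word) - 1)
        return int(iw[steps, 4 * word[:-1] + word[1:]].sum())

    def pvalue_of_int(self, score: int) -> float:
        idx = score - self.min_score
        if idx < 0:
            return 1.0
        if idx >= len(self.sf):
            # above the maximum achievable score: the tail collapses onto the
            # best word(s)
            idx = len(self.sf) - 1
        return float(self.sf[idx])

    def pvalue(self, score: float) -> float:
        return self.pvalue_of_int(int(np.rint(score / self.resolution)))


def default_resolution(pwm: PWM) -> float:
    score_range = float(
        (pwm.weights.max(axis=1) - pwm.weights.min(axis=1)).sum()
    )
    if score_range <= 0:
        return 1.0
    return score_range / PVALUE_GRID_BINS


def pwm_pvalue_table(pwm: PWM, resolution: float | None = None) -> PvalueTable:
    """Position-wise dynamic program for the exact score tail distribution.

    Mononucleotide matrices use the PWM's background letter probabilities;
    dinucleotide matrices assume i.i.d. uniform letters (each word of k+1
    bases has probability 4^-(k+1)) with a 4-state DP over the previous
    letter.
    """
    if resolution is None:
        resolution = default_resolution(pwm)
    if resolution <= 0:
        raise FeatureError("resolution must be positive")
    iw = np.rint(pwm.weights / resolution).astype(np.int64)

    if pwm.order == PWMOrder.MONO:
        bg = pwm.background
        probs = np.array([1.0])
        base = 0
        for p in range(pwm.n_steps):
            row = iw[p]
            lo, hi = int(row.min()), int(row.max())
            new = np.zeros(len(probs) + hi - lo)
            for letter in range(4):
                shift = int(row[letter]) - lo
                new[shift : shift + len(probs)] += bg[letter] * probs
            probs = new
            base += lo
    else:
        # state: previous letter; uniform 1/4 letter background
        probs_by_letter = [np.array([0.25]) for _ in range(4)]
        base = 0
        for step in range(pwm.n_steps):
            row = iw[step]
            lo, hi = int(row.min()), int(row.max())
            size = len(probs_by_letter[0]) + hi - lo
            new = [np.zeros(size) for _ in range(4)]
            for prev in range(4):
                for nxt in range(4):
                    shift = int(row[4 * prev + nxt]) - lo
                    new[nxt][shift : shift + len(probs_by_letter[prev])] += (
                        0.25 * probs_by_letter[prev]
                    )
            probs_by_letter = new
            base += lo
        probs = np.sum(probs_by_letter, axis=0)

    sf = np.cumsum(probs[::-1])[::-1]
    sf = np.minimum(sf, 1.0)  # guard against float drift above 1
    return PvalueTable(
        motif_id=pwm.motif_id,
        order=pwm.order,
        resolution=resolution,
        int_weights=iw,
        min_score=base,
        sf=sf,
    )


# ---------------------------------------------------------------------------
# best-hit scoring


def _revcomp_int_weights(table: PvalueTable) -> np.ndarray:
    """Integer weights scoring the reverse complement of a window directly."""
    iw = table.int_weights
    if table.order == PWMOrder.MONO:
        return iw[::-1, ::-1]
    # di: step s scoring (a, b) maps to step n-1-s scoring (comp b, comp a)
    n_steps, _ = iw.shape
    out = np.empty_like(iw)
    for step in range(n_steps):
        for a in range(4):
            for b in range(4):
                out[step, 4 * a + b] = iw[n_steps - 1 - step, 4 * (3 - b) + (3 - a)]
    return out


def _seq_to_idx(sequence: str) -> np.ndarray:
    return np.array([DNA_INDEX[c] for c in sequence], dtype=np.int64)


def best_hit_pvalue(
    sequence: str,
    snv_position: int,
    allele: str,
    pwm: PWM,
    table: PvalueTable,
    both_strands: bool = True,
) -> float:
    """Minimum motif P-value over all windows overlapping the substituted
    base, on both strands, with ``allele`` substituted in."""
    seq_idx = _seq_to_idx(sequence)
    seq_idx[snv_position] = DNA_INDEX[allele]
    W = pwm.width
    lo = max(0, snv_position - W + 1)
    hi = min(snv_position, len(sequence) - W)
    if hi < lo:
        raise FeatureError(
            f"no window of width {W} covering position {snv_position} fits in "
            f"a sequence of length {len(sequence)}"
        )
    iw_rc = _revcomp_int_weights(table) if both_strands else None
    best = None
    for start in range(lo, hi + 1):
        window = seq_idx[start : start + W]
        score = table.score_int(window)
        best = score if best is None else max(best, score)
        if both_strands:
            if pwm.order == PWMOrder.MONO:
                rc = int(iw_rc[np.arange(W), window].sum())
            else:
                steps = np.arange(W - 1)
                rc = int(iw_rc[steps, 4 * window[:-1] + window[1:]].sum())
            best = max(best, rc)
    return table.pvalue_of_int(best)


# ---------------------------------------------------------------------------
# feature matrices


@dataclass
class FeatureMatrix:
    """SNV-by-feature table with per-column provider provenance."""

    df: pd.DataFrame
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if list(self.df.columns) != list(self.provenance.keys()):
            raise FeatureError("provenance keys must match columns in order")
        if self.df.isna().any().any():
            raise FeatureError("feature matrix contains missing values")

    @property
    def snv_index(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def columns_with_tag(self, *tags: str) -> list[str]:
        return [c for c, t in self.provenance.items() if t in tags]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "#provenance\t"
                + "\t".join(f"{c}={t}" for c, t in self.provenance.items())
                + "\n"
            )
            self.df.to_csv(fh, sep="\t", index_label="snv_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#provenance\t"):
                raise FeatureError(f"{path}: missing provenance header")
            provenance = dict(
                item.split("=", 1) for item in header.split("\t")[1:]
            )
            df = pd.read_csv(fh, sep="\t", index_col="snv_id")
        return cls(df=df, provenance=provenance)


def assemble(*providers: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of feature matrices over one SNV index."""
    if not providers:
        raise FeatureError("no providers given")
    index = providers[0].snv_index
    for p in providers[1:]:
        if p.snv_index != index:
            raise FeatureError("providers disagree on the SNV index")
    df = pd.concat([p.df for p in providers], axis=1)
    provenance: dict[str, str] = {}
    for p in providers:
        for c, t in p.provenance.items():
            if c in provenance:
                raise FeatureError(f"duplicate feature name {c!r}")
            provenance[c] = t
    return FeatureMatrix(df=df, provenance=provenance)


# ---------------------------------------------------------------------------
# motif provider


def _mono_best_hit_arrays(
    seq_idx: np.ndarray, table: PvalueTable, both_strands: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position best-hit P-values for the reference base and each
    substituted base (vectorised mononucleotide fast path).

    Returns ``(p_ref, p_sub)`` where ``p_ref`` has shape (L,) and ``p_sub``
    shape (L, 4) over substituted letters (column of the reference letter
    equals ``p_ref``).
    """
    iw = table.int_weights
    W = iw.shape[0]
    L = len(seq_idx)
    if L < W:
        raise FeatureError(f"sequence of length {L} shorter than motif width {W}")
    starts = np.arange(L - W + 1)
    win = starts[:, None] + np.arange(W)[None, :]
    offsets = np.arange(W)[None, :]
    scores = [iw[offsets, seq_idx[win]].sum(axis=1)]
    matrices = [iw]
    if both_strands:
        iw_rc = iw[::-1, ::-1]
        scores.append(iw_rc[offsets, seq_idx[win]].sum(axis=1))
        matrices.append(iw_rc)

    p_ref = np.empty(L)
    p_sub = np.empty((L, 4))
    for pos in range(L):
        s_lo = max(0, pos - W + 1)
        s_hi = min(pos, L - W)
        sel = slice(s_lo, s_hi + 1)
        rel = pos - starts[sel]
        ref = seq_idx[pos]
        best_by_letter = np.full(4, np.iinfo(np.int64).min)
        for mat, sc in zip(matrices, scores):
            base = sc[sel]
            for letter in range(4):
                cand = base + mat[rel, letter] - mat[rel, ref]
                best_by_letter[letter] = max(best_by_letter[letter], cand.max())
        for letter in range(4):
            p_sub[pos, letter] = table.pvalue_of_int(int(best_by_letter[letter]))
        p_ref[pos] = p_sub[pos, ref]
    return p_ref, p_sub


def motif_features(
    dataset,
    pwms: Sequence[PWM],
    resolution: float | None = None,
    both_strands: bool = True,
) -> FeatureMatrix:
    """Two columns per motif: -log10 of the best-hit P-value for the
    reference allele, and log10(P_alt / P_ref) (positive when the
    substitution weakens the best binding site)."""
    tables = {p.motif_id: pwm_pvalue_table(p, resolution) for p in pwms}
    per_reporter: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for rep in dataset.reporters:
        seq_idx = _seq_to_idx(rep.sequence)
        per_reporter[rep.reporter_id] = {}
        for pwm in pwms:
            table = tables[pwm.motif_id]
            if pwm.order == PWMOrder.MONO:
                per_reporter[rep.reporter_id][pwm.motif_id] = _mono_best_hit_arrays(
                    seq_idx, table, both_strands
                )
            else:
                L = rep.length
                p_ref = np.empty(L)
                p_sub = np.empty((L, 4))
                for pos in range(L):
                    for letter, base in enumerate("ACGT"):
                        p_sub[pos, letter] = best_hit_pvalue(
                            rep.sequence, pos, base, pwm, table, both_strands
                        )
                    p_ref[pos] = p_sub[pos, seq_idx[pos]]
                per_reporter[rep.reporter_id][pwm.motif_id] = (p_ref, p_sub)

    snv_ids = [s.snv_id for s in dataset.snvs]
    columns: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for pwm in pwms:
        ref_col = np.empty(len(snv_ids))
        fc_col = np.empty(len(snv_ids))
        for i, snv in enumerate(dataset.snvs):
            p_ref, p_sub = per_reporter[snv.reporter_id][pwm.motif_id]
            pr = p_ref[snv.position]
            pa = p_sub[snv.position, DNA_INDEX[snv.alt_allele]]
            ref_col[i] = -np.log10(pr)
            fc_col[i] = np.log10(pa / pr)
        columns[f"{pwm.motif_id}:neglog10_pref"] = ref_col
        provenance[f"{pwm.motif_id}:neglog10_pref"] = "motif"
        columns[f"{pwm.motif_id}:log10_fc"] = fc_col
        provenance[f"{pwm.motif_id}:log10_fc"] = "motif"
    return FeatureMatrix(df=pd.DataFrame(columns, index=snv_ids),
                         provenance=provenance)


# ---------------------------------------------------------------------------
# track providers


def _group_tracks(tracks: Sequence[SignalTrack]) -> dict[str, list[SignalTrack]]:
    grouped: dict[str, list[SignalTrack]] = {}
    for t in tracks:
        grouped.setdefault(t.track_id, []).append(t)
    return grouped


def _interval_values(
    segments: Sequence[SignalTrack], chrom: str, start: int, end: int,
    track_id: str,
) -> np.ndarray:
    """Per-base values over [start, end); uncovered bases contribute 0."""
    values = np.zeros(end - start)
    covered = np.zeros(end - start, dtype=bool)
    for seg in segments:
        if seg.chrom != chrom:
            continue
        a = max(start, seg.start)
        b = min(end, seg.end)
        if a < b:
            values[a - start : b - start] = seg.values[a - seg.start : b - seg.start]
            covered[a - start : b - start] = True
    if not covered.all():
        logger.warning(
            "track %s: %d of %d bases of %s:%d-%d uncovered, treated as 0",
            track_id, int((~covered).sum()), end - start, chrom, start, end,
        )
    return values


def _minmax_scale(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)  # degenerate scaling maps to 0
    return (values - lo) / (hi - lo)


def _track_like_features(
    dataset,
    tracks: Sequence[SignalTrack],
    coordinate_of,
    tag_scaled: str,
    tag_mean: str,
) -> FeatureMatrix:
    grouped = _group_tracks(tracks)
    snv_ids = [s.snv_id for s in dataset.snvs]
    columns: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for tid, segments in grouped.items():
        scaled_col = np.empty(len(snv_ids))
        mean_col = np.empty(len(snv_ids))
        per_rep: dict[str, tuple[np.ndarray, float]] = {}
        for rep in dataset.reporters:
            coords = np.array([coordinate_of(rep, pos) for pos in range(rep.length)])
            # fetch per-base values at the (possibly remapped) coordinates
            raw = np.empty(rep.length)
            # group contiguous coordinate runs for efficient interval fetches
            run_start = 0
            for i in range(1, rep.length + 1):
                if i == rep.length or coords[i] != coords[i - 1] + 1:
                    chrom = rep.chrom if coordinate_of is _identity_coord else segments[0].chrom
                    vals = _interval_values(
                        segments, chrom, int(coords[run_start]),
                        int(coords[i - 1]) + 1, tid,
                    )
                    raw[run_start:i] = vals
                    run_start = i
            per_rep[rep.reporter_id] = (_minmax_scale(raw), float(raw.mean()))
        for i, snv in enumerate(dataset.snvs):
            scaled, mean = per_rep[snv.reporter_id]
            scaled_col[i] = scaled[snv.position]
            mean_col[i] = mean
        columns[f"{tid}:scaled"] = scaled_col
        provenance[f"{tid}:scaled"] = tag_scaled
        columns[f"{tid}:mean"] = mean_col
        provenance[f"{tid}:mean"] = tag_mean
    return FeatureMatrix(df=pd.DataFrame(columns, index=snv_ids),
                         provenance=provenance)


def _identity_coord(rep, pos: int) -> int:
    return rep.start + pos


def track_features(dataset, tracks: Sequence[SignalTrack]) -> FeatureMatrix:
    """Per track: a per-reporter min-max-scaled value column and a constant
    per-reporter unscaled-mean column (2 columns per track)."""
    return _track_like_features(dataset, tracks, _identity_coord, "track", "track_mean")


def alien_features(
    dataset, alien_tracks: Sequence[SignalTrack], alien_region_length: int
) -> FeatureMatrix:
    """Track-style features looked up at wrapped alien coordinates."""

    def alien_coord(rep, pos: int) -> int:
        return (rep.start + pos) % alien_region_length

    return _track_like_features(dataset, alien_tracks, alien_coord, "alien", "alien")


def shuffle_within_reporters(
    features: FeatureMatrix,
    dataset,
    rng: np.random.Generator,
    tags: Sequence[str] = ("alien",),
) -> FeatureMatrix:
    """Ablation: permute per-position feature values within each reporter for
    columns carrying the given provenance tags, destroying their local
    autocorrelation while preserving each reporter's value distribution.
    Position atomicity is kept (the three alleles at a position move
    together); per-reporter constant columns are unaffected by construction.
    """
    df = features.df.copy()
    target_cols = features.columns_with_tag(*tags)
    row_pos = np.array([s.position for s in dataset.snvs])
    row_rep = np.array([s.reporter_id for s in dataset.snvs])
    for rep in dataset.reporters:
        rows = np.where(row_rep == rep.reporter_id)[0]
        positions = np.unique(row_pos[rows])
        perm = rng.permutation(len(positions))
        pos_map = {int(p): int(positions[perm[i]]) for i, p in enumerate(positions)}
        for col in target_cols:
            col_vals = df[col].to_numpy().copy()
            by_pos = {}
            for r in rows:
                by_pos.setdefault(int(row_pos[r]), []).append(r)
            orig = {p: col_vals[rs[0]] for p, rs in by_pos.items()}
            for p, rs in by_pos.items():
                col_vals[rs] = orig[pos_map[p]]
            df[col] = col_vals
    return FeatureMatrix(df=df, provenance=dict(features.provenance))
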