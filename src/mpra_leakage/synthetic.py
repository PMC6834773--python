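"""Synthetic saturation-mutagenesis MPRA datasets.

The generator emulates the statistical structure of a multi-reporter
saturation-mutagenesis experiment without any external download:

* ~14 reporters of a few hundred bp, every possible SNV measured
  (3 alternative alleles per position);
* transcription-factor binding sites planted from a small PWM set, so that
  SNVs with significant expression effects are spatially clustered within
  binding-site-sized segments;
* a regulatory:neutral class balance of about 2:7 at the 0.1 confidence
  threshold, hit by bisection on the effect scale;
* locally autocorrelated signal tracks — some informative (derived from the
  planted-site indicator), some *alien* (the same smoothed-noise process with
  no relation to the effects, a negative control for layout leakage);
* optionally one reporter sequence duplicated under a second cell type, the
  analogue of a promoter assayed twice.

Per-SNV confidences are built the way MPRA pipelines build them: the latent
expression effect is ``effect_scale * ΔPWMscore`` at planted sites plus
Gaussian noise, a two-sided P-value of the effect is taken against a
conservative null (noise inflated by ``null_sd_inflation``), and the capped
negative log10 P-value is normalised to [0, 1].  The conservative null keeps
pure-noise positions essentially always below the 0.1 regulatory threshold,
so regulatory SNVs arise (almost) only inside planted sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .core import (
    DNA_ALPHABET,
    DNA_INDEX,
    PWM,
    PWMOrder,
    REGULATORY_CONFIDENCE_THRESHOLD,
    Reporter,
    ReporterKind,
    SignalTrack,
    SNVRecord,
)
from . import io as mio

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The generator configuration is infeasible."""


class SiteAnnotation(NamedTuple):
    """Ground-truth planted binding site, reporter-local half-open interval."""

    reporter_id: str
    start: int
    end: int
    motif_id: str


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the scale of the emulated assay: 14 reporters of 300 bp
    (plus a duplicated reporter standing in for a promoter assayed in two
    cell types), five planted sites per reporter, and a pooled regulatory
    fraction targeted at 2/9.
    """

    n_reporters: int = 14
    reporter_length: int = 420
    n_planted_sites_per_reporter: int = 3
    pwm_set: list[PWM] | None = None
    effect_scale: float = 3.0
    noise_sd: float = 1.0
    target_regulatory_fraction: float | None = 2.0 / 9.0
    track_autocorrelation_bp: float = 80.0
    alien_autocorrelation_bp: float | None = 80.0
    track_noise_amp: float = 0.5
    # informative tracks emulate assays from many cell types: a track's
    # signal amplitude at a given locus is drawn from
    # U(1 - track_relevance_variation, 1), so each track is informative for
    # some reporters and near-irrelevant for others, while its local
    # autocorrelation (the leakage carrier) is unaffected
    track_relevance_variation: float = 1.0
    n_informative_tracks: int = 4
    n_alien_tracks: int = 8
    duplicate_reporter: bool = True
    # sized so the last reporter wraps around (the analogue of one reporter
    # lying beyond the alien chromosome) while wrapped intervals stay far
    # (>> autocorrelation width) from every other reporter's interval —
    # otherwise wrapped near-collisions would correlate "independent"
    # features across reporters
    alien_region_length: int = 21001
    confidence_cap: float = 5.0
    null_sd_inflation: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reporters < 1 or self.reporter_length < 1:
            raise ConfigError("need at least one reporter with positive length")
        if self.noise_sd < 0 or self.effect_scale < 0:
            raise ConfigError("noise_sd and effect_scale must be non-negative")
        if self.target_regulatory_fraction is not None and not (
            0.0 < self.target_regulatory_fraction < 1.0
        ):
            raise ConfigError("target_regulatory_fraction must lie in (0, 1)")


@dataclass
class SyntheticDataset:
    reporters: list[Reporter]
    snvs: list[SNVRecord]
    informative_tracks: list[SignalTrack]
    alien_tracks: list[SignalTrack]
    site_annotations: list[SiteAnnotation]
    config: SyntheticConfig
    effect_scale_used: float
    pwms: list[PWM]

    @property
    def reporter_by_id(self) -> dict[str, Reporter]:
        return {r.reporter_id: r for r in self.reporters}

    @property
    def snv_ids(self) -> list[str]:
        return [s.snv_id for s in self.snvs]

    def confidences(self) -> np.ndarray:
        return np.array([s.confidence for s in self.snvs])

    def directions(self) -> np.ndarray:
        return np.array([s.direction for s in self.snvs], dtype=int)

    def regulatory_fraction(self) -> float:
        return float(np.mean(self.confidences() >= REGULATORY_CONFIDENCE_THRESHOLD))


# ---------------------------------------------------------------------------
# default PWM set


def default_pwm_set(seed: int = 0, n_pwms: int = 5,
                    widths: Sequence[int] = (33, 34, 35, 36, 37)) -> list[PWM]:
    """Informative mononucleotide matrices with peaked columns, modelling
    clustered binding segments (regulatory elements) rather than single
    short motifs.

    Column base probabilities are Dirichlet(0.3) draws floored at 1e-3, giving
    elements where most substitutions change the score substantially — the
    regime in which binding-site disruption drives expression effects.
    """
    rng = np.random.default_rng([int(seed), 97])
    pwms = []
    for j in range(n_pwms):
        width = widths[j % len(widths)]
        probs = rng.dirichlet([0.3] * 4, size=width)
        probs = np.maximum(probs, 1e-3)
        probs /= probs.sum(axis=1, keepdims=True)
        weights = np.log(probs / 0.25)
        pwms.append(PWM(motif_id=f"SYN_MOTIF_{j:02d}", order=PWMOrder.MONO,
                        weights=weights))
    return pwms


# ---------------------------------------------------------------------------
# site planting


def plant_sites(
    sequence: str,
    pwm_set: Sequence[PWM],
    n_sites: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Plant ``n_sites`` non-overlapping motif occurrences into ``sequence``.

    Motifs are taken from ``pwm_set`` cycling in a shuffled order; each site's
    bases are replaced by a sample from the PWM's implied per-position letter
    probabilities.  Returns the mutated sequence and ``(start, end, motif_id)``
    annotations.  Raises :class:`ConfigError` if a non-overlapping placement
    cannot be found within ``max_attempts`` draws.
    """
    if n_sites == 0:
        return sequence, []
    length = len(sequence)
    order = [pwm_set[k % len(pwm_set)] for k in range(n_sites)]
    rng.shuffle(order)
    if sum(p.width for p in order) > length:
        raise ConfigError("planted sites cannot fit in the reporter")

    placed: list[tuple[int, int, PWM]] = []
    attempts = 0
    for pwm in order:
        w = pwm.width
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise ConfigError(
                    f"could not place {n_sites} non-overlapping sites in "
                    f"{length} bp after {max_attempts} attempts"
                )
            start = int(rng.integers(0, length - w + 1))
            if all(start + w <= s or start >= e for s, e, _ in placed):
                placed.append((start, start + w, pwm))
                break

    seq = list(sequence)
    annotations: list[tuple[int, int, str]] = []
    for start, end, pwm in sorted(placed):
        probs = pwm.letter_probabilities()
        for offset in range(pwm.width):
            seq[start + offset] = DNA_ALPHABET[
                rng.choice(4, p=probs[offset])
            ]
        annotations.append((start, end, pwm.motif_id))
    return "".join(seq), annotations


# ---------------------------------------------------------------------------
# effect assignment


def _alt_alleles(ref: str) -> list[str]:
    return [c for c in DNA_ALPHABET if c != ref]


def _site_score_deltas(
    sequence: str,
    annotations: Sequence[tuple[int, int, str]],
    pwm_by_id: dict[str, PWM],
) -> np.ndarray:
    """Per-(position, alt) PWM score change caused by the substitution.

    Zero outside planted sites.  Shape (L, 3); alt alleles are ordered
    alphabetically among the three bases different from the reference.
    """
    length = len(sequence)
    deltas = np.zeros((length, 3))
    seq_idx = np.array([DNA_INDEX[c] for c in sequence])
    for start, end, motif_id in annotations:
        pwm = pwm_by_id[motif_id]
        w = pwm.weights
        for pos in range(start, end):
            rel = pos - start
            ref = seq_idx[pos]
            for j, alt in enumerate(_alt_alleles(sequence[pos])):
                a = DNA_INDEX[alt]
                if pwm.order == PWMOrder.MONO:
                    deltas[pos, j] = w[rel, a] - w[rel, ref]
                else:
                    # a substitution touches at most two dinucleotide steps
                    d = 0.0
                    for step in (rel - 1, rel):
                        if 0 <= step < pwm.n_steps:
                            left = seq_idx[start + step]
                            right = seq_idx[start + step + 1]
                            if step == rel - 1:
                                d += w[step, 4 * left + a] - w[step, 4 * left + ref]
                            else:
                                d += w[step, 4 * a + right] - w[step, 4 * ref + right]
                    deltas[pos, j] = d
    return deltas


def _confidence_from_effect(
    effects: np.ndarray, noise_sd: float, null_sd_inflation: float, cap: float
) -> np.ndarray:
    """Capped, normalised -log10 two-sided P-value of the latent effect."""
    null_sd = null_sd_inflation * noise_sd
    if null_sd <= 0:
        z = np.where(np.abs(effects) > 0, np.inf, 0.0)
    else:
        z = np.abs(effects) / null_sd
    pvals = np.maximum(2.0 * stats.norm.sf(z), 1e-300)
    return np.minimum(-np.log10(pvals), cap) / cap


def _records_from_effects(
    reporter_id: str,
    sequence: str,
    effects: np.ndarray,
    confidences: np.ndarray,
) -> list[SNVRecord]:
    records = []
    for pos in range(len(sequence)):
        ref = sequence[pos]
        for j, alt in enumerate(_alt_alleles(ref)):
            conf = float(confidences[pos, j])
            regulatory = conf >= REGULATORY_CONFIDENCE_THRESHOLD
            direction = int(np.sign(effects[pos, j])) if regulatory else 0
            if regulatory and direction == 0:
                direction = 1  # zero effect cannot reach the threshold unless sd=0
            records.append(
                SNVRecord(reporter_id, pos, ref, alt, conf, direction)
            )
    return records


def assign_effects(
    reporter: Reporter,
    site_annotations: Sequence[tuple[int, int, str]],
    pwm_set: Sequence[PWM],
    effect_scale: float,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    null_sd_inflation: float = 5.0,
    confidence_cap: float = 5.0,
) -> list[SNVRecord]:
    """Assign a confidence and direction to every possible SNV of a reporter.

    The latent effect of each substitution is ``effect_scale`` times the PWM
    score change at an overlapping planted site (zero elsewhere) plus
    ``Normal(0, noise_sd)`` noise; significance is called against the
    conservative null ``Normal(0, null_sd_inflation * noise_sd)``.
    """
    for start, end, _ in site_annotations:
        if start < 0 or end > reporter.length:
            raise ConfigError("site annotation outside reporter bounds")
    pwm_by_id = {p.motif_id: p for p in pwm_set}
    deltas = _site_score_deltas(reporter.sequence, site_annotations, pwm_by_id)
    noise = rng.normal(0.0, noise_sd, size=deltas.shape) if noise_sd > 0 else np.zeros(deltas.shape)
    effects = effect_scale * deltas + noise
    conf = _confidence_from_effect(effects, noise_sd, null_sd_inflation, confidence_cap)
    return _records_from_effects(reporter.reporter_id, reporter.sequence, effects, conf)


def _solve_effect_scale(
    deltas: np.ndarray,
    noise: np.ndarray,
    noise_sd: float,
    null_sd_inflation: float,
    cap: float,
    target: float,
    tolerance: float = 0.03,
) -> float:
    """Bisection on the effect scale so the pooled regulatory fraction hits
    ``target``.  Deterministic given the (fixed) deltas and noise draws."""

    def frac(scale: float) -> float:
        conf = _confidence_from_effect(scale * deltas + noise, noise_sd,
                                       null_sd_inflation, cap)
        return float(np.mean(conf >= REGULATORY_CONFIDENCE_THRESHOLD))

    lo, hi = 0.0, 1.0
    while frac(hi) < target and hi < 1e6:
        hi *= 2.0
    achieved = frac(hi)
    if achieved < target:
        if achieved >= target - tolerance:
            logger.warning(
                "regulatory fraction saturates at %.3f below target %.3f",
                achieved, target,
            )
            return hi
        raise ConfigError(
            f"regulatory fraction saturates at {achieved:.3f}, more than "
            f"{tolerance} below the target {target:.3f}; plant more/wider sites"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    scale = hi
    achieved = frac(scale)
    if abs(achieved - target) > tolerance:
        raise ConfigError(
            f"bisection achieved regulatory fraction {achieved:.3f}, outside "
            f"±{tolerance} of target {target:.3f}"
        )
    return scale


# ---------------------------------------------------------------------------
# tracks


def _smoothed(values: np.ndarray, width_bp: float) -> np.ndarray:
    sigma = max(width_bp, 1e-9) / 2.0
    return gaussian_filter1d(values, sigma=sigma, mode="constant")


def _unit_sd_smooth_noise(length: int, width_bp: float,
                          rng: np.random.Generator) -> np.ndarray:
    noise = _smoothed(rng.standard_normal(length), width_bp)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def generate_tracks(
    reporters: Sequence[Reporter],
    site_annotations: Sequence[SiteAnnotation],
    config: SyntheticConfig,
) -> tuple[list[SignalTrack], list[SignalTrack]]:
    """Build informative and alien signal tracks.

    Informative tracks: the planted-site 0/1 indicator convolved with a
    Gaussian kernel of width ``track_autocorrelation_bp`` (peak-normalised),
    plus smoothed unit-sd noise scaled by ``track_noise_amp`` — a stand-in
    for extended-read ChIP/ATAC coverage over true regulatory elements.

    Alien tracks: the identical smoothed-noise process on a separate
    coordinate system, with no site term — locally autocorrelated but carrying
    no information about the effects.

    A duplicated reporter shares its genomic interval, hence reads the same
    track values as its twin (same locus assayed in another cell type).
    """
    width = config.track_autocorrelation_bp
    ann_by_reporter: dict[str, list[SiteAnnotation]] = {}
    for ann in site_annotations:
        ann_by_reporter.setdefault(ann.reporter_id, []).append(ann)

    # unique genomic intervals (duplicated reporters collapse onto one)
    intervals: list[tuple[str, int, int]] = []
    indicator_by_interval: dict[tuple[str, int, int], np.ndarray] = {}
    for rep in reporters:
        key = (rep.chrom, rep.start, rep.end)
        if key in indicator_by_interval:
            continue
        intervals.append(key)
        indicator = np.zeros(rep.length)
        for ann in ann_by_reporter.get(rep.reporter_id, []):
            indicator[ann.start : ann.end] = 1.0
        indicator_by_interval[key] = indicator

    informative: list[SignalTrack] = []
    for j in range(config.n_informative_tracks):
        for k, key in enumerate(intervals):
            chrom, start, end = key
            rng = np.random.default_rng([int(config.seed), 2, j, k])
            lo = 1.0 - config.track_relevance_variation
            relevance = float(rng.uniform(lo, 1.0))
            signal = _smoothed(indicator_by_interval[key], width)
            peak = signal.max()
            if peak > 0:
                signal = signal / peak
            values = relevance * signal
            if config.track_noise_amp > 0:
                values = values + config.track_noise_amp * _unit_sd_smooth_noise(
                    end - start, width, rng
                )
            informative.append(SignalTrack(f"informative_{j:02d}", chrom, start, values))

    alien_width = (config.alien_autocorrelation_bp
                   if config.alien_autocorrelation_bp is not None else width)
    alien: list[SignalTrack] = []
    for j in range(config.n_alien_tracks):
        rng = np.random.default_rng([int(config.seed), 3, j])
        values = _unit_sd_smooth_noise(config.alien_region_length, alien_width, rng)
        alien.append(SignalTrack(f"alien_{j:02d}", "chrALIEN", 0, values))
    return informative, alien


# ---------------------------------------------------------------------------
# dataset generation


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset, deterministic given the config.

    Each reporter draws from its own RNG stream keyed by the master seed and
    the reporter index, so enlarging ``n_reporters`` never perturbs earlier
    reporters.  When ``target_regulatory_fraction`` is set, the effect scale
    is solved by bisection over the pooled dataset; otherwise
    ``config.effect_scale`` is used as-is.
    """
    pwms = config.pwm_set if config.pwm_set is not None else default_pwm_set(config.seed)
    pwm_by_id = {p.motif_id: p for p in pwms}

    reporters: list[Reporter] = []
    annotations: list[SiteAnnotation] = []
    deltas_per_reporter: list[np.ndarray] = []
    noise_per_reporter: list[np.ndarray] = []

    for i in range(config.n_reporters):
        rng = np.random.default_rng([int(config.seed), 1, i])
        rep_id = f"R{i + 1:02d}"
        base_seq = "".join(rng.choice(list(DNA_ALPHABET), size=config.reporter_length))
        seq, anns = plant_sites(
            base_seq, pwms, config.n_planted_sites_per_reporter, rng
        )
        kind = ReporterKind.ENHANCER if i < 5 else ReporterKind.PROMOTER
        rep = Reporter(
            reporter_id=rep_id,
            cell_type=f"ct{i + 1:02d}",
            kind=kind,
            chrom="chrS",
            start=2000 + i * 1500,
            end=2000 + i * 1500 + config.reporter_length,
            sequence=seq,
        )
        reporters.append(rep)
        annotations.extend(SiteAnnotation(rep_id, s, e, m) for s, e, m in anns)
        deltas_per_reporter.append(_site_score_deltas(seq, anns, pwm_by_id))
        noise_per_reporter.append(
            rng.normal(0.0, config.noise_sd, size=(config.reporter_length, 3))
            if config.noise_sd > 0
            else np.zeros((config.reporter_length, 3))
        )

    if config.duplicate_reporter:
        base = reporters[-1]
        dup = Reporter(
            reporter_id=f"{base.reporter_id}b",
            cell_type=f"ct{config.n_reporters + 1:02d}",
            kind=base.kind,
            chrom=base.chrom,
            start=base.start,
            end=base.end,
            sequence=base.sequence,
        )
        rng_dup = np.random.default_rng([int(config.seed), 4])
        reporters.append(dup)
        base_anns = [a for a in annotations if a.reporter_id == base.reporter_id]
        annotations.extend(
            SiteAnnotation(dup.reporter_id, a.start, a.end, a.motif_id)
            for a in base_anns
        )
        deltas_per_reporter.append(deltas_per_reporter[-1])
        noise_per_reporter.append(
            rng_dup.normal(0.0, config.noise_sd, size=(config.reporter_length, 3))
            if config.noise_sd > 0
            else np.zeros((config.reporter_length, 3))
        )

    deltas = np.concatenate(deltas_per_reporter, axis=0)
    noise = np.concatenate(noise_per_reporter, axis=0)

    if config.target_regulatory_fraction is not None:
        scale = _solve_effect_scale(
            deltas, noise, config.noise_sd, config.null_sd_inflation,
            config.confidence_cap, config.target_regulatory_fraction,
        )
    else:
        scale = config.effect_scale

    snvs: list[SNVRecord] = []
    offset = 0
    for rep, d, z in zip(reporters, deltas_per_reporter, noise_per_reporter):
        effects = scale * d + z
        conf = _confidence_from_effect(
            effects, config.noise_sd, config.null_sd_inflation, config.confidence_cap
        )
        snvs.extend(_records_from_effects(rep.reporter_id, rep.sequence, effects, conf))
        offset += rep.length

    informative, alien = generate_tracks(reporters, annotations, config)
    return SyntheticDataset(
        reporters=reporters,
        snvs=snvs,
        informative_tracks=informative,
        alien_tracks=alien,
        site_annotations=annotations,
        config=config,
        effect_scale_used=scale,
        pwms=pwms,
    )


# ---------------------------------------------------------------------------
# on-disk form (the same formats the readers consume)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_fasta(
        {r.reporter_id: r.sequence for r in dataset.reporters},
        outdir / "reporters.fasta",
    )
    mio.write_snv_table(dataset.snvs, outdir / "snvs.tsv")
    with open(outdir / "reporters.tsv", "w") as fh:
        fh.write("reporter_id\tcell_type\tkind\tchrom\tstart\tend\n")
        for r in dataset.reporters:
            fh.write(
                f"{r.reporter_id}\t{r.cell_type}\t{r.kind.value}\t{r.chrom}\t"
                f"{r.start}\t{r.end}\n"
            )
    by_track: dict[str, list[SignalTrack]] = {}
    for t in dataset.informative_tracks + dataset.alien_tracks:
        by_track.setdefault(t.track_id, []).append(t)
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for tid, segs in by_track.items():
        mio.write_bedgraph(segs, tracks_dir / f"{tid}.bedgraph")
    with open(outdir / "sites.tsv", "w") as fh:
        fh.write("reporter_id\tstart\tend\tmotif_id\n")
        for a in dataset.site_annotations:
            fh.write(f"{a.reporter_id}\t{a.start}\t{a.end}\t{a.motif_id}\n")
    mio.write_pwm_collection(dataset.pwms, outdir / "pwms.txt")
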