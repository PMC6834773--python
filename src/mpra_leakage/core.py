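"""Domain types shared by every stage of the pipeline.

The unit of measurement is a single-nucleotide variant (SNV) inside a cloned
regulatory *reporter* sequence (a promoter or enhancer tested in a massively
parallel reporter assay).  Each SNV carries a confidence score on [0, 1]
summarising the strength of its expression effect and a direction label:
+1 (upregulating), -1 (downregulating) or 0 (no significant effect).  SNVs
with confidence >= 0.1 are labelled regulatory; the confidence threshold and
the direction label are coupled by construction and the types below enforce
that coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

DNA_ALPHABET = "ACGT"
DNA_INDEX = {c: i for i, c in enumerate(DNA_ALPHABET)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: confidence at or above this value marks an SNV as regulatory
REGULATORY_CONFIDENCE_THRESHOLD = 0.1


class ReporterKind(str, Enum):
    PROMOTER = "promoter"
    ENHANCER = "enhancer"


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class Reporter:
    """A tested regulatory sequence.

    Coordinates are 0-based half-open genome coordinates; ``sequence`` spans
    exactly ``[start, end)``.
    """

    reporter_id: str
    cell_type: str
    kind: ReporterKind
    chrom: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValidationError(f"{self.reporter_id}: negative coordinates")
        if len(self.sequence) == 0:
            raise ValidationError(f"{self.reporter_id}: empty sequence")
        if self.end - self.start != len(self.sequence):
            raise ValidationError(
                f"{self.reporter_id}: end - start = {self.end - self.start} "
                f"but sequence length is {len(self.sequence)}"
            )
        bad = set(self.sequence) - set(DNA_ALPHABET)
        if bad:
            raise ValidationError(
                f"{self.reporter_id}: non-ACGT characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SNVRecord:
    """One substitution with its measured effect.

    ``position`` is the 0-based offset of the substituted base within its
    reporter.  ``direction`` is +/-1 only when ``confidence`` reaches the
    regulatory threshold of 0.1, and 0 otherwise.
    """

    reporter_id: str
    position: int
    ref_allele: str
    alt_allele: str
    confidence: float
    direction: int

    def __post_init__(self) -> None:
        ident = f"{self.reporter_id}:{self.position}:{self.ref_allele}>{self.alt_allele}"
        if self.ref_allele not in DNA_INDEX or self.alt_allele not in DNA_INDEX:
            raise ValidationError(f"{ident}: alleles must be single A/C/G/T bases")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{ident}: alt allele equals ref allele")
        if self.position < 0:
            raise ValidationError(f"{ident}: negative position")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"{ident}: confidence {self.confidence} outside [0, 1]"
            )
        if self.direction not in (-1, 0, 1):
            raise ValidationError(f"{ident}: direction {self.direction} not in -1/0/1")
        if self.direction != 0 and self.confidence < REGULATORY_CONFIDENCE_THRESHOLD:
            raise ValidationError(
                f"{ident}: direction {self.direction} with confidence "
                f"{self.confidence} < {REGULATORY_CONFIDENCE_THRESHOLD}"
            )
        if self.direction == 0 and self.confidence >= REGULATORY_CONFIDENCE_THRESHOLD:
            raise ValidationError(
                f"{ident}: direction 0 with confidence "
                f"{self.confidence} >= {REGULATORY_CONFIDENCE_THRESHOLD}"
            )

    @property
    def snv_id(self) -> str:
        return f"{self.reporter_id}:{self.position}:{self.ref_allele}>{self.alt_allele}"

    @property
    def is_regulatory(self) -> bool:
        return self.confidence >= REGULATORY_CONFIDENCE_THRESHOLD


@dataclass
class SignalTrack:
    """Per-base signal over one contiguous genomic interval.

    A logical track (e.g. one ChIP-seq experiment) may be represented by
    several ``SignalTrack`` segments sharing a ``track_id``.
    """

    track_id: str
    chrom: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError(f"{self.track_id}: values must be a non-empty vector")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.track_id}: non-finite signal values")
        if self.start < 0:
            raise ValidationError(f"{self.track_id}: negative start")

    @property
    def end(self) -> int:
        return self.start + len(self.values)


class PWMOrder(str, Enum):
    MONO = "mono"
    DI = "di"


@dataclass
class PWM:
    """Additive log-odds motif model.

    ``weights`` has one row per scored step: ``width`` rows of 4 columns for a
    mononucleotide matrix, or ``width - 1`` rows of 16 columns for a
    dinucleotide matrix scoring overlapping dinucleotides (a di-matrix of k
    steps covers k + 1 bases).  ``background`` is a probability vector over
    the step alphabet.
    """

    motif_id: str
    order: PWMOrder
    weights: np.ndarray
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        alpha = 4 if self.order == PWMOrder.MONO else 16
        if self.weights.ndim != 2 or self.weights.shape[1] != alpha:
            raise ValidationError(
                f"{self.motif_id}: expected {alpha} columns, got shape "
                f"{self.weights.shape}"
            )
        if self.weights.shape[0] < 1:
            raise ValidationError(f"{self.motif_id}: empty matrix")
        if self.background is None:
            self.background = np.full(alpha, 1.0 / alpha)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (alpha,):
            raise ValidationError(f"{self.motif_id}: background size mismatch")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValidationError(f"{self.motif_id}: background does not sum to 1")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError(f"{self.motif_id}: non-finite weights")

    @property
    def n_steps(self) -> int:
        return self.weights.shape[0]

    @property
    def width(self) -> int:
        """Motif width in bases."""
        return self.n_steps if self.order == PWMOrder.MONO else self.n_steps + 1

    def letter_probabilities(self) -> np.ndarray:
        """Per-position base probabilities implied by the log-odds weights.

        For a mononucleotide matrix this inverts the log-odds transform
        (p ∝ background · exp(weight)) column-normalised per position.  For a
        dinucleotide matrix the marginal of the first base of each step is
        used, which is adequate for sampling site sequences.
        """
        if self.order == PWMOrder.MONO:
            p = self.background[None, :] * np.exp(self.weights)
            return p / p.sum(axis=1, keepdims=True)
        # di: collapse each step's 16 dinucleotide odds onto the leading base,
        # and the last step additionally onto its trailing base
        probs = np.zeros((self.width, 4))
        p = self.background[None, :] * np.exp(self.weights)
        p = p / p.sum(axis=1, keepdims=True)
        for step in range(self.n_steps):
            probs[step] = p[step].reshape(4, 4).sum(axis=1)
        probs[-1] = p[-1].reshape(4, 4).sum(axis=0)
        return probs


MetricName = str


@dataclass
class EvalReport:
    """The metric battery for one scope (a reporter id, or ``"pooled"``).

    ``metrics`` maps MAE_c, MSE_c, ME_c, PCC_c, SCC_c, PCC_d, SCC_d, AUCROC
    and AUPRC to floats; a metric that is undefined on the scope (constant
    vector, single class) is present with value NaN and an explanatory flag.
    """

    scope: str
    metrics: Mapping[MetricName, float]
    n: int = 0
    n_positive: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for key in ("AUCROC", "AUPRC"):
            v = self.metrics.get(key)
            if v is not None and np.isfinite(v) and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{self.scope}: {key}={v} outside [0, 1]")
        for key in ("PCC_c", "SCC_c", "PCC_d", "SCC_d"):
            v = self.metrics.get(key)
            if v is not None and np.isfinite(v) and not (-1.0 - 1e-12 <= v <= 1.0 + 1e-12):
                raise ValidationError(f"{self.scope}: {key}={v} outside [-1, 1]")
        for key in ("MAE_c", "MSE_c"):
            v = self.metrics.get(key)
            if v is not None and np.isfinite(v) and v < 0:
                raise ValidationError(f"{self.scope}: {key}={v} negative")
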