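"""Positionally-weighted PWM scoring and allele-aware motif disruption calls.

The matrix score used throughout this package is a consensus-normalised,
positionally-weighted product.  For a motif of length ``L`` with per-position
base frequencies ``f[i][b]`` and positional weights ``w[i]``,

    s(seq) = prod_i ( f[i][seq_i] / max_b f[i][b] ) ** w[i]

so ``s`` ranges over [0, 1]: the consensus sequence (an argmax base at every
position) scores exactly 1, and any base with frequency 0 (pseudocounts
disabled) annihilates the product to 0.  Positional weights default to
information content normalised by the maximum-IC column, so the most
constrained position carries weight 1 and uninformative positions contribute
little; a uniform-weight mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

WeightScheme = Literal["ic", "uniform"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """A position frequency matrix with positional weights.

    ``matrix`` has shape (L, 4) in A, C, G, T order; each row sums to 1.
    ``pseudocount`` is added to every frequency and the row renormalised
    before scoring; set it to 0.0 for exact-zero annihilation semantics.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 1e-3
    weight_scheme: WeightScheme = "ic"
    weights: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if m.shape[0] < 4:
            raise ValueError(f"PWM {self.name!r}: motif length must be >= 4")
        if np.any(m < 0):
            raise ValueError(f"PWM {self.name!r}: negative frequencies")
        sums = m.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: rows must sum to 1 (got {sums})")
        object.__setattr__(self, "matrix", m)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self),) or np.any(w < 0):
                raise ValueError("weights must be non-negative, one per position")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def effective_matrix(self) -> np.ndarray:
        """Frequencies after pseudocount addition and renormalisation."""
        if self.pseudocount == 0.0:
            return self.matrix
        m = self.matrix + self.pseudocount
        return m / m.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.effective_matrix, axis=1))

    def information_content(self) -> np.ndarray:
        """Per-position IC in bits, 2 + sum_b f log2 f, after pseudocount."""
        m = self.effective_matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(m > 0, m * np.log2(m), 0.0)
        return 2.0 + plogp.sum(axis=1)

    def reverse_complement(self) -> "PWM":
        rc = self.matrix[::-1, ::-1].copy()
        w = None if self.weights is None else self.weights[::-1].copy()
        return replace(self, matrix=rc, weights=w)


@dataclass(frozen=True)
class MotifHit:
    pwm_name: str
    score: float
    offset: int
    strand: str
    allele: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError(f"motif score out of [0, 1]: {self.score}")


@dataclass(frozen=True)
class DisruptionCall:
    variant_id: str
    pwm_name: str
    ref_hit: MotifHit
    alt_hit: MotifHit
    delta: float
    is_match: bool
    is_disruption: bool
    stronger_allele: str

    def __post_init__(self) -> None:
        if self.is_disruption and not self.is_match:
            raise ValueError("is_disruption requires is_match")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


def positional_weights(pwm: PWM) -> np.ndarray:
    """Positional weights for a PWM under its configured scheme.

    The default ``ic`` scheme sets w[i] = IC_i / max_j IC_j so the most
    informative position gets weight 1.  ``uniform`` returns all ones,
    reducing the score to a plain consensus-normalised product.
    """
    if pwm.weights is not None:
        return pwm.weights
    if pwm.weight_scheme == "uniform":
        return np.ones(len(pwm))
    ic = pwm.information_content()
    top = ic.max()
    if top <= 0:
        raise ValueError(
            f"PWM {pwm.name!r} has zero information content at every position; "
            "use weight_scheme='uniform' for flat matrices"
        )
    return ic / top


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[c] for c in seq.upper()), dtype=np.intp,
                           count=len(seq))
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGT character: {exc}") from exc


def motif_score(pwm: PWM, seq: str, *, n_policy: Literal["error", "zero"] = "error") -> float:
    """Score a sequence of exactly the motif length; result lies in [0, 1]."""
    if len(seq) != len(pwm):
        raise ValueError(f"sequence length {len(seq)} != motif length {len(pwm)}")
    su = seq.upper()
    if any(c not in _BASE_INDEX for c in su):
        if n_policy == "zero":
            return 0.0
        raise ValueError(f"ambiguous base in {seq!r}; set n_policy='zero' to score 0")
    idx = _encode(su)
    m = pwm.effective_matrix
    w = positional_weights(pwm)
    col_max = m.max(axis=1)
    ratio = m[np.arange(len(pwm)), idx] / col_max
    zero = ratio == 0.0
    # 0**0 = 1 by convention: a zero-weight position cannot annihilate
    if np.any(zero & (w > 0)):
        return 0.0
    keep = ~zero
    return float(np.prod(ratio[keep] ** w[keep]))


def _score_window_offsets(pwm: PWM, window: str) -> np.ndarray:
    L = len(pwm)
    return np.array([motif_score(pwm, window[o:o + L]) for o in range(len(window) - L + 1)])


def scan_best_hit(pwm: PWM, window_seq: str, *, strands: str = "both",
                  allele: str | None = None) -> MotifHit:
    """Best motif placement over all offsets (and both strands by default).

    Ties break toward the smallest offset, then the + strand.  Minus-strand
    scores are computed by scoring the reverse complement of the placement
    window against the PWM.
    """
    L = len(pwm)
    if len(window_seq) < L:
        raise ValueError("window shorter than motif")
    best = None
    n_off = len(window_seq) - L + 1
    for offset in range(n_off):
        sub = window_seq[offset:offset + L]
        candidates = [("+", sub)]
        if strands == "both":
            candidates.append(("-", reverse_complement(sub)))
        for strand, s in candidates:
            score = motif_score(pwm, s)
            key = (-score, offset, strand)
            if best is None or key < best[0]:
                best = (key, MotifHit(pwm.name, score, offset, strand, allele))
    assert best is not None
    return best[1]


def score_allele_disruption(
    pwm: PWM,
    context_seq: str,
    variant_pos: int,
    ref: str,
    alt: str,
    *,
    tau_match: float = 0.8,
    tau_delta: float = 0.2,
) -> DisruptionCall:
    """Allele-aware disruption call for a variant embedded in its context.

    ``variant_pos`` is the 0-based index of the variant within
    ``context_seq``; the context must cover at least L-1 bases on each side
    so every motif placement covering the variant is scanned.  Only
    placements covering the variant position are considered, so the call
    reflects the alleles rather than flanking sequence.
    """
    L = len(pwm)
    if context_seq[variant_pos].upper() != ref.upper():
        raise ValueError(
            f"reference allele {ref!r} disagrees with context base "
            f"{context_seq[variant_pos]!r} at position {variant_pos}"
        )
    lo = max(0, variant_pos - L + 1)
    hi = min(len(context_seq), variant_pos + L)
    if hi - lo < L:
        raise ValueError("context does not cover a full motif placement over the variant")

    def best_for(allele: str) -> MotifHit:
        seq = context_seq[:variant_pos] + allele + context_seq[variant_pos + 1:]
        hit = scan_best_hit(pwm, seq[lo:hi], allele=allele)
        return MotifHit(hit.pwm_name, hit.score, hit.offset + lo, hit.strand, allele)

    ref_hit = best_for(ref.upper())
    alt_hit = best_for(alt.upper())
    delta = abs(ref_hit.score - alt_hit.score)
    is_match = max(ref_hit.score, alt_hit.score) >= tau_match
    return DisruptionCall(
        variant_id="",
        pwm_name=pwm.name,
        ref_hit=ref_hit,
        alt_hit=alt_hit,
        delta=delta,
        is_match=is_match,
        is_disruption=is_match and delta >= tau_delta,
        stronger_allele=ref.upper() if ref_hit.score >= alt_hit.score else alt.upper(),
    )


# ---------------------------------------------------------------------------
# JASPAR-like text IO
# ---------------------------------------------------------------------------

def write_pwms(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write PWMs in a JASPAR-like dialect: >name, then four base rows."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{v:.6f}" for v in pwm.matrix[:, bi])
                fh.write(f"{base} [ {row} ]\n")


def read_pwms(path: str | Path, *, pseudocount: float = 1e-3,
              weight_scheme: WeightScheme = "ic") -> list[PWM]:
    """Read a JASPAR-like PWM file; count matrices are normalised to frequencies."""
    pwms: list[PWM] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        if set(rows) != set(BASES):
            raise ValueError(f"PWM {name!r}: expected rows for A, C, G, T")
        m = np.array([rows[b] for b in BASES], dtype=float).T
        sums = m.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError(f"PWM {name!r}: zero column sum")
        pwms.append(PWM(name, m / sums, pseudocount=pseudocount,
                        weight_scheme=weight_scheme))
        name, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
            else:
                base, rest = line.split(None, 1)
                vals = [float(tok) for tok in rest.strip("[] \t").split()]
                rows[base.upper()] = vals
    flush()
    return pwms


def disruption_table(calls: Sequence[DisruptionCall]):
    """Disruption calls as a tidy DataFrame (one row per variant x PWM)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "variant": [c.variant_id for c in calls],
            "pwm": [c.pwm_name for c in calls],
            "s_ref": [c.ref_hit.score for c in calls],
            "s_alt": [c.alt_hit.score for c in calls],
            "delta": [c.delta for c in calls],
            "strand": [c.ref_hit.strand if c.ref_hit.score >= c.alt_hit.score
                       else c.alt_hit.strand for c in calls],
            "offset": [c.ref_hit.offset if c.ref_hit.score >= c.alt_hit.score
                       else c.alt_hit.offset for c in calls],
            "is_match": [c.is_match for c in calls],
            "is_disruption": [c.is_disruption for c in calls],
            "stronger_allele": [c.stronger_allele for c in calls],
        }
    )
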