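"""Position-weight-matrix scoring.

Carries a minimal log-odds PWM implementation plus the bundled matrices used
elsewhere in the package:

* splice-donor and splice-acceptor models built from textbook mammalian
  consensus frequencies (donor ``MAG|GTRAGT``, acceptor
  pyrimidine-rich ``...NYAG|G``), used to score inferred exon junctions in
  spliced 5' transductions;
* three toy transcription-factor matrices (FOX-, RXR- and PU.1-like core
  motifs) for variant-effect scanning.  They are consensus-derived
  caricatures of the real motif families, adequate for directional
  variant-effect tests but not calibrated against any motif database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp

_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class PWM:
    """Log-odds position weight matrix over A/C/G/T columns."""

    name: str
    log_odds: np.ndarray = field(repr=False)  # shape (width, 4)

    @classmethod
    def from_frequencies(
        cls,
        name: str,
        freqs: list[dict[str, float]],
        background: float = 0.25,
        pseudocount: float = 0.01,
    ) -> "PWM":
        width = len(freqs)
        mat = np.empty((width, 4))
        for i, col in enumerate(freqs):
            probs = np.array([col.get(b, 0.0) for b in "ACGT"], dtype=float)
            probs = probs + pseudocount
            probs = probs / probs.sum()
            mat[i] = np.log2(probs / background)
        return cls(name, mat)

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    def score(self, window: str) -> float:
        """Log-odds score of one window (must match the PWM width)."""
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != PWM width {self.width}")
        return float(sum(self.log_odds[i, _IDX[b]] for i, b in enumerate(window)))

    def score_normalized(self, window: str) -> float:
        """Score rescaled to [0, 1] between the worst and best possible window."""
        smin = float(self.log_odds.min(axis=1).sum())
        smax = float(self.log_odds.max(axis=1).sum())
        return (self.score(window) - smin) / (smax - smin)

    def best_score(self, seq: str, both_strands: bool = True) -> float:
        """Maximum window score over the sequence (optionally both strands)."""
        w = self.width
        if len(seq) < w:
            raise ValueError("sequence shorter than PWM width")
        strands = [seq, revcomp(seq)] if both_strands else [seq]
        return max(
            self.score(s[i : i + w]) for s in strands for i in range(len(s) - w + 1)
        )


def _cols(spec: list[tuple[float, float, float, float]]) -> list[dict[str, float]]:
    return [dict(zip("ACGT", c)) for c in spec]


# 9-nt splice donor model covering the last 3 exonic and first 6 intronic
# bases (MAG | GTRAGT).  Frequencies follow the canonical mammalian 5'ss
# consensus profile.
SPLICE_DONOR = PWM.from_frequencies(
    "splice_donor",
    _cols(
        [
            (0.35, 0.35, 0.19, 0.11),  # M
            (0.60, 0.13, 0.14, 0.13),  # A
            (0.09, 0.05, 0.78, 0.08),  # G
            (0.00, 0.00, 1.00, 0.00),  # G (invariant)
            (0.00, 0.00, 0.00, 1.00),  # T (invariant)
            (0.53, 0.03, 0.42, 0.02),  # R
            (0.71, 0.08, 0.12, 0.09),  # A
            (0.07, 0.06, 0.81, 0.06),  # G
            (0.16, 0.15, 0.22, 0.47),  # T
        ]
    ),
)

# 15-nt splice acceptor model: 11 pyrimidine-tract bases, one spacer, the
# invariant AG, and the first exonic base (G-biased).
SPLICE_ACCEPTOR = PWM.from_frequencies(
    "splice_acceptor",
    _cols(
        [(0.09, 0.33, 0.09, 0.49)] * 11  # Y-rich tract
        + [
            (0.24, 0.28, 0.22, 0.26),  # N
            (1.00, 0.00, 0.00, 0.00),  # A (invariant)
            (0.00, 0.00, 1.00, 0.00),  # G (invariant)
            (0.26, 0.16, 0.42, 0.16),  # exonic G bias
        ]
    ),
)


def _tf(name: str, consensus: str, degenerate: dict[int, dict[str, float]] | None = None) -> PWM:
    cols: list[dict[str, float]] = []
    for i, b in enumerate(consensus):
        if degenerate and i in degenerate:
            cols.append(degenerate[i])
        else:
            col = {x: 0.05 for x in "ACGT"}
            col[b] = 0.85
            cols.append(col)
    return PWM.from_frequencies(name, cols)


#: Toy transcription-factor matrices for variant-effect scanning.  The
#: RXR-like matrix has a degenerate third position (G preferred, C tolerated,
#: T disfavored) so that a T->C change there raises the score.
TF_PWMS: dict[str, PWM] = {
    "FOX-like": _tf("FOX-like", "TGTTTAC"),
    "RXR-like": _tf(
        "RXR-like",
        "AGGTCA",
        degenerate={2: {"A": 0.05, "C": 0.30, "G": 0.60, "T": 0.05}},
    ),
    "PU.1-like": _tf("PU.1-like", "GAGGAA"),
}
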