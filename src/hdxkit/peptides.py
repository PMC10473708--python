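"""Peptide records and exchangeable-amide bookkeeping.

In HDX-MS the observable unit is the peptic peptide: a span of the
protein identified after quench-and-digest, whose centroid mass shift
reports the summed deuterium occupancy of its backbone amides.  Not
every residue contributes an exchangeable amide: prolines have none,
and the N-terminal amide(s) of a peptide lose deuterium so fast during
workup that they are conventionally excluded from the countable maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CoordinateError, InputError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Mass increment per retained deuteron (Da): the 2H-1H mass difference.
MASS_SHIFT_PER_D = 1.00628


def exchangeable_amides(sequence: str, n_term_exclusion: int = 1) -> int:
    """Count the backbone amides of ``sequence`` that can retain deuterium.

    The count is ``len(sequence) - n_term_exclusion`` minus the prolines
    at positions ``n_term_exclusion + 1 .. end`` (1-based).  The default
    excludes only the peptide's first residue; some laboratories exclude
    the first two (``n_term_exclusion=2``).

    Raises
    ------
    InputError
        If the sequence is empty or contains a non-standard letter.
    """
    if not sequence:
        raise InputError("empty peptide sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise InputError(f"unknown residue letter(s) {sorted(bad)} in {sequence!r}")
    if n_term_exclusion < 1:
        raise InputError("n_term_exclusion must be >= 1")
    body = sequence[n_term_exclusion:]
    return max(0, len(body) - body.count("P"))


@dataclass(frozen=True)
class PeptideRecord:
    """One peptic peptide in full-protein (1-based, inclusive) coordinates."""

    protein_id: str
    start: int
    end: int
    sequence: str
    max_uptake: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CoordinateError(f"peptide end {self.end} < start {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise CoordinateError(
                f"peptide {self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} does not match span"
            )
        if self.max_uptake < 0:
            raise InputError("max_uptake must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def make_peptide(
    protein_id: str,
    start: int,
    sequence: str,
    n_term_exclusion: int = 1,
) -> PeptideRecord:
    """Build a :class:`PeptideRecord` with ``max_uptake`` derived from the
    sequence under the stated N-terminal-exclusion convention."""
    return PeptideRecord(
        protein_id=protein_id,
        start=start,
        end=start + len(sequence) - 1,
        sequence=sequence,
        max_uptake=exchangeable_amides(sequence, n_term_exclusion),
    )


def random_protein(length: int, seed: int = 0, proline_fraction: float = 0.05) -> str:
    """Draw a random amino-acid sequence for simulation work.

    Prolines are placed at ``proline_fraction`` of positions (uniformly at
    random, never at position 1) so peptic maps carry realistic gaps in
    exchangeable amides; the remaining positions are drawn uniformly from
    the other 19 letters.
    """
    if length < 1:
        raise InputError("length must be >= 1")
    rng = np.random.default_rng(seed)
    letters = sorted(AMINO_ACIDS - {"P"})
    seq = list(rng.choice(letters, size=length))
    n_pro = int(round(proline_fraction * length))
    if n_pro and length > 1:
        pos = rng.choice(np.arange(1, length), size=min(n_pro, length - 1), replace=False)
        for p in pos:
            seq[p] = "P"
    return "".join(seq)
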