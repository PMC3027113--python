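"""Sequence-profile parsing and conservation features.

A position-specific scoring matrix (PSSM) produced by an iterated profile
search carries, for every sequence position, 20 log-odds scores and 20
weighted observed percentages (0-100). Seven conservation features describe a
substitution: the score and the percentage for the wild-type and the mutant
residue, their mutant-minus-wild differences, and the Shannon entropy of the
position's amino-acid frequencies (in bits; lower entropy = more conserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Column order of the profile-search ASCII PSSM output.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: k for k, aa in enumerate(ALPHABET)}


class ProfileError(ValueError):
    """Raised for malformed profile input."""


@dataclass
class ProfileMatrix:
    """Per-position profile: log-odds scores, observed percentages, frequencies.

    ``scores`` and ``percents`` are (length, 20) arrays in :data:`ALPHABET`
    column order. ``frequencies`` are the percentages / 100 renormalized to sum
    to 1 per position; positions whose percentages are all zero are recorded in
    ``zero_rows`` and get a zero frequency vector (entropy 0).
    """

    scores: np.ndarray
    percents: np.ndarray
    zero_rows: list[int] = field(default_factory=list)   # 1-based positions

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.percents = np.asarray(self.percents, dtype=float)
        if self.scores.shape != self.percents.shape or self.scores.shape[1:] != (20,):
            raise ProfileError("scores/percents must both be (length, 20)")
        if np.any(self.percents < 0):
            raise ProfileError("negative observed percentage")
        sums = self.percents.sum(axis=1)
        self.zero_rows = [int(i) + 1 for i in np.nonzero(sums == 0)[0]]
        freq = np.zeros_like(self.percents)
        nz = sums > 0
        freq[nz] = self.percents[nz] / sums[nz, None]
        self.frequencies = freq

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def _row(self, pos: int) -> int:
        if not 1 <= pos <= self.length:
            raise ProfileError(f"position {pos} outside profile (1..{self.length})")
        return pos - 1

    def entropy(self, pos: int) -> float:
        """Conservation score of a position (bits)."""
        return conservation_score(self.frequencies[self._row(pos)])

    def score_of(self, pos: int, aa: str) -> float:
        return float(self.scores[self._row(pos), _aa_col(aa)])

    def percent_of(self, pos: int, aa: str) -> float:
        return float(self.percents[self._row(pos), _aa_col(aa)])


def _aa_col(aa: str) -> int:
    try:
        return AA_INDEX[aa]
    except KeyError:
        raise ProfileError(f"unknown amino acid {aa!r}") from None


def conservation_score(freqs: np.ndarray) -> float:
    """Shannon entropy (base 2) of a 20-vector of frequencies.

    0 * log2(0) is taken as 0; an all-zero vector (degenerate profile row)
    scores 0.
    """
    p = np.asarray(freqs, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative frequency")
    if p.sum() > 1.0 + 1e-6:
        raise ValueError("frequencies sum to more than 1")
    nz = p[p > 0]
    if nz.size == 0:
        return 0.0
    return float(-np.sum(nz * np.log2(nz)))


@dataclass(frozen=True)
class ConservationFeatures:
    """The seven per-substitution conservation features."""

    pssm_wild: float
    pssm_mutant: float
    freq_wild: float
    freq_mutant: float
    det_pssm: float      # mutant - wild
    det_freq: float      # mutant - wild
    entropy: float       # bits

    def as_tuple(self) -> tuple[float, ...]:
        return (self.pssm_wild, self.pssm_mutant, self.freq_wild,
                self.freq_mutant, self.det_pssm, self.det_freq, self.entropy)


def conservation_features(profile: ProfileMatrix, pos: int,
                          wild: str, mutant: str) -> ConservationFeatures:
    """Conservation block for a substitution wild->mutant at ``pos`` (1-based).

    The profile row need not agree with the wild-type residue; differences are
    mutant minus wild.
    """
    pw = profile.score_of(pos, wild)
    pm = profile.score_of(pos, mutant)
    fw = profile.percent_of(pos, wild)
    fm = profile.percent_of(pos, mutant)
    return ConservationFeatures(
        pssm_wild=pw, pssm_mutant=pm, freq_wild=fw, freq_mutant=fm,
        det_pssm=pm - pw, det_freq=fm - fw, entropy=profile.entropy(pos),
    )


def parse_pssm(profile_source: str | Path) -> ProfileMatrix:
    """Parse an ASCII PSSM file into a :class:`ProfileMatrix`.

    Two dialects are accepted: the classic profile-search ASCII matrix (rows:
    position, residue, 20 scores, 20 percentages, trailing statistics) and a
    plain TSV fallback with header ``pos  aa  <20 score cols>  <20 pct cols>``.
    """
    path = Path(profile_source)
    lines = path.read_text().splitlines()
    if lines and lines[0].lower().startswith("pos\t"):
        return _parse_tsv(lines, path)
    return _parse_ascii(lines, path)


def _parse_ascii(lines: list[str], path: Path) -> ProfileMatrix:
    scores, percents = [], []
    expected_idx = 1
    for lineno, line in enumerate(lines, start=1):
        parts = line.split()
        if len(parts) < 42:
            continue
        try:
            idx = int(parts[0])
        except ValueError:
            continue
        if parts[1].upper() not in AA_INDEX and parts[1].upper() != "X":
            continue
        try:
            values = [float(v) for v in parts[2:42]]
        except ValueError as exc:
            raise ProfileError(f"{path}:{lineno}: malformed profile row ({exc})") from None
        if idx != expected_idx:
            raise ProfileError(
                f"{path}:{lineno}: position {idx} out of order (expected {expected_idx})"
            )
        expected_idx += 1
        scores.append(values[:20])
        percents.append(values[20:])
    if not scores:
        raise ProfileError(f"{path}: no profile rows found")
    return ProfileMatrix(scores=np.array(scores), percents=np.array(percents))


def _parse_tsv(lines: list[str], path: Path) -> ProfileMatrix:
    scores, percents = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 42:
            raise ProfileError(f"{path}:{lineno}: expected 42 columns, got {len(parts)}")
        try:
            values = [float(v) for v in parts[2:]]
        except ValueError as exc:
            raise ProfileError(f"{path}:{lineno}: malformed row ({exc})") from None
        scores.append(values[:20])
        percents.append(values[20:])
    if not scores:
        raise ProfileError(f"{path}: no profile rows found")
    return ProfileMatrix(scores=np.array(scores), percents=np.array(percents))
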