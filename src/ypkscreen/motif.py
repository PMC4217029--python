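"""Position-weight-matrix model of an AGC-kinase phospho-acceptor motif.

The screen's first tier is a constrained PWM describing the preferred
sequence context of the phospho-acceptor serine/threonine of the yeast
kinase Ypk1: arginine is invariant at offsets -5 and -3 relative to the
acceptor (offset 0), and a hydrophobic residue (V, I or F) at +1 is
preferred but not required.  A window of residues around a candidate S/T is
scored as a summed log-odds against a background composition, and the raw
score is normalised onto [0, 1] by the matrix's own exhaustive score range
so that a fixed likelihood cutoff (0.7 by convention) can be applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
PAD: str = "-"
UNKNOWN: str = "X"
ACCEPTORS: frozenset[str] = frozenset("ST")
HYDROPHOBIC_PLUS1: frozenset[str] = frozenset("VIF")

#: invariant residues of the core motif: Arg at -5 and -3, S/T at 0
DEFAULT_CONSTRAINED: dict[int, frozenset[str]] = {
    -5: frozenset("R"),
    -3: frozenset("R"),
    0: ACCEPTORS,
}
#: preferred but not required: hydrophobic +1
DEFAULT_PREFERENCE: dict[int, frozenset[str]] = {1: HYDROPHOBIC_PLUS1}

#: default window geometry, offsets relative to the acceptor
DEFAULT_OFFSETS: tuple[int, ...] = tuple(range(-5, 5))


class MotifError(ValueError):
    """Raised on invalid motif windows, matrices or scoring inputs."""


@dataclass(frozen=True)
class MotifWindow:
    """Residues at fixed offsets around a phospho-acceptor (offset 0).

    Positions beyond the ends of the source protein are padded with ``-``;
    padding may occur only at the extremes of the window.
    """

    residues: tuple[str, ...]
    offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.offsets):
            raise MotifError("residues and offsets must have equal length")
        if 0 not in self.offsets:
            raise MotifError("window must include the acceptor offset 0")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise MotifError("offsets must be strictly increasing")
        allowed = set(AMINO_ACIDS) | {PAD, UNKNOWN}
        bad = [r for r in self.residues if r not in allowed]
        if bad:
            raise MotifError(f"residues outside alphabet: {bad!r}")
        # padding only at the extremes
        core = [r for r in self.residues]
        lo = 0
        while lo < len(core) and core[lo] == PAD:
            lo += 1
        hi = len(core)
        while hi > lo and core[hi - 1] == PAD:
            hi -= 1
        if PAD in core[lo:hi]:
            raise MotifError("padding symbols allowed only at window extremes")

    @classmethod
    def from_string(cls, s: str, offsets: Sequence[int] | None = None) -> "MotifWindow":
        offs = tuple(offsets) if offsets is not None else tuple(
            range(-(len(s) // 2), len(s) - len(s) // 2)
        )
        return cls(tuple(s.upper()), offs)

    def residue_at(self, offset: int) -> str:
        try:
            return self.residues[self.offsets.index(offset)]
        except ValueError:
            return PAD

    def __str__(self) -> str:
        return "".join(self.residues)


@dataclass
class MotifMatrix:
    """Per-offset residue probabilities with hard constraints and preferences.

    ``probs`` is an (N, 20) array over :data:`AMINO_ACIDS`; each row sums to
    one.  ``constrained_offsets`` holds the invariant residues of the core
    motif and ``preference_offsets`` the soft preferences; both must refer to
    offsets the matrix actually covers.
    """

    offsets: tuple[int, ...]
    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 1.0
    constrained_offsets: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_CONSTRAINED)
    )
    preference_offsets: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_PREFERENCE)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = len(self.offsets)
        if self.probs.shape != (n, 20):
            raise MotifError(f"probs must have shape ({n}, 20)")
        if self.background.shape != (20,):
            raise MotifError("background must be a 20-vector")
        if (self.probs < 0).any() or (self.background < 0).any():
            raise MotifError("probabilities must be nonnegative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise MotifError("per-offset probabilities must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise MotifError("background must sum to 1")
        if self.pseudocount < 0:
            raise MotifError("pseudocount must be nonnegative")
        for mapping in (self.constrained_offsets, self.preference_offsets):
            for o in mapping:
                if o not in self.offsets:
                    raise MotifError(f"constrained/preference offset {o} not in matrix")

    # -- scoring machinery -------------------------------------------------

    @property
    def logodds(self) -> np.ndarray:
        """(N, 20) array of ln(p / background); -inf where p == 0."""
        with np.errstate(divide="ignore"):
            return np.log(self.probs) - np.log(self.background)

    def score_range(self) -> tuple[float, float]:
        """Exhaustive (min, max) of the summed log-odds over all windows.

        The optimum of a per-position sum is attained per position, so the
        range is the sum of per-offset extremes.  Zero-probability entries
        (possible at pseudocount 0) are excluded from the minimum so the
        range stays finite; windows containing such residues score -inf and
        clip to likelihood 0.
        """
        lo = self.logodds
        finite = np.where(np.isfinite(lo), lo, np.nan)
        mins = np.nanmin(finite, axis=1)
        maxs = np.nanmax(finite, axis=1)
        return float(mins.sum()), float(maxs.sum())

    def consensus(self) -> MotifWindow:
        """Window of per-offset argmax residues (maximises the raw score)."""
        idx = self.probs.argmax(axis=1)
        return MotifWindow(tuple(AMINO_ACIDS[i] for i in idx), self.offsets)

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        lines = [
            f"#pseudocount\t{self.pseudocount!r}",
            "#background\t" + ",".join(
                f"{a}:{float(self.background[i])!r}" for i, a in enumerate(AMINO_ACIDS)
            ),
            "#constrained\t" + ";".join(
                f"{o}:{''.join(sorted(s))}" for o, s in sorted(self.constrained_offsets.items())
            ),
            "#preference\t" + ";".join(
                f"{o}:{''.join(sorted(s))}" for o, s in sorted(self.preference_offsets.items())
            ),
            "offset\t" + "\t".join(AMINO_ACIDS),
        ]
        for i, o in enumerate(self.offsets):
            lines.append(str(o) + "\t" + "\t".join(repr(float(p)) for p in self.probs[i]))
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifMatrix":
        meta: dict[str, str] = {}
        offsets: list[int] = []
        rows: list[list[float]] = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                meta[key] = val
            elif line.startswith("offset"):
                continue
            else:
                parts = line.split("\t")
                offsets.append(int(parts[0]))
                rows.append([float(x) for x in parts[1:]])
        background = np.empty(20)
        for item in meta["background"].split(","):
            a, _, v = item.partition(":")
            background[AA_INDEX[a]] = float(v)

        def parse_sets(s: str) -> dict[int, frozenset[str]]:
            out: dict[int, frozenset[str]] = {}
            for item in s.split(";"):
                if item:
                    o, _, res = item.partition(":")
                    out[int(o)] = frozenset(res)
            return out

        return cls(
            offsets=tuple(offsets),
            probs=np.array(rows),
            background=background,
            pseudocount=float(meta["pseudocount"]),
            constrained_offsets=parse_sets(meta.get("constrained", "")),
            preference_offsets=parse_sets(meta.get("preference", "")),
        )


@dataclass(frozen=True)
class SiteScore:
    """Score of one candidate window: raw log-odds (nats), min-max
    normalised likelihood in [0, 1], and the two constraint flags."""

    raw_logodds: float
    likelihood: float
    core_ok: bool
    plus1_hydrophobic: bool


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20)


def background_from_sequences(sequences: Iterable[str]) -> np.ndarray:
    """Residue frequencies of a scanned sequence set (X and pads ignored);
    falls back to uniform if no countable residues are present."""
    counts = np.zeros(20)
    for seq in sequences:
        for ch in seq.upper():
            i = AA_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        return uniform_background()
    return counts / total


def build_pwm(
    training_windows: Sequence[MotifWindow],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    constrained_offsets: Mapping[int, frozenset[str]] | None = None,
    preference_offsets: Mapping[int, frozenset[str]] | None = None,
) -> MotifMatrix:
    """Estimate a PWM from aligned training windows by Laplace-smoothed
    counting.

    ``probs[o][a] = (count(a at o) + pseudocount) /
    (effective_count(o) + 20 * pseudocount)`` where padded positions are
    excluded from the counts at their offsets.
    """
    if not training_windows:
        raise MotifError("empty training set")
    if pseudocount < 0:
        raise MotifError("negative pseudocount")
    offsets = training_windows[0].offsets
    for w in training_windows[1:]:
        if w.offsets != offsets:
            raise MotifError("inconsistent offsets across training windows")
    counts = np.zeros((len(offsets), 20))
    for w in training_windows:
        for i, r in enumerate(w.residues):
            if r in (PAD, UNKNOWN):
                continue
            counts[i, AA_INDEX[r]] += 1
    effective = counts.sum(axis=1, keepdims=True)
    denom = effective + 20.0 * pseudocount
    if (denom == 0).any():
        # offset seen only as padding and pseudocount 0: fall back to uniform
        probs = np.where(denom > 0, (counts + pseudocount) / np.where(denom > 0, denom, 1.0), 1.0 / 20)
    else:
        probs = (counts + pseudocount) / denom
    bg = uniform_background() if background is None else np.asarray(background, float)
    return MotifMatrix(
        offsets=offsets,
        probs=probs,
        background=bg,
        pseudocount=pseudocount,
        constrained_offsets=dict(constrained_offsets or DEFAULT_CONSTRAINED),
        preference_offsets=dict(preference_offsets or DEFAULT_PREFERENCE),
    )


def check_constraints(
    window: MotifWindow,
    mode: str = "core",
    constrained_offsets: Mapping[int, frozenset[str]] | None = None,
    preference_offsets: Mapping[int, frozenset[str]] | None = None,
) -> tuple[bool, bool, bool]:
    """Evaluate the invariant core and the +1 preference on a window.

    Returns ``(core_ok, plus1_hydrophobic, accepted)``.  In mode ``core``
    acceptance requires only the invariant residues; in mode ``strict`` the
    +1 hydrophobic preference is required as well.  Padded (or unknown)
    residues at required positions fail.
    """
    if mode not in ("core", "strict"):
        raise MotifError(f"invalid mode {mode!r}")
    constrained = constrained_offsets or DEFAULT_CONSTRAINED
    preference = preference_offsets or DEFAULT_PREFERENCE
    core_ok = all(window.residue_at(o) in allowed for o, allowed in constrained.items())
    plus1 = all(window.residue_at(o) in allowed for o, allowed in preference.items())
    accepted = core_ok and (plus1 or mode == "core")
    return core_ok, plus1, accepted


def score_window(matrix: MotifMatrix, window: MotifWindow) -> SiteScore:
    """Score a window against the matrix.

    Raw score is the summed per-offset ln(p/background); padded and unknown
    positions contribute zero.  Likelihood is the raw score min-max
    normalised by the matrix's exhaustive score range (a degenerate range
    maps everything to 1.0), clipped to [0, 1] so padded windows stay on
    scale.
    """
    if window.offsets != matrix.offsets:
        raise MotifError("window offsets do not match matrix offsets")
    lo = matrix.logodds
    raw = 0.0
    for i, r in enumerate(window.residues):
        if r in (PAD, UNKNOWN):
            continue
        raw += float(lo[i, AA_INDEX[r]])
    raw_min, raw_max = matrix.score_range()
    if raw_max > raw_min:
        likelihood = min(1.0, max(0.0, (raw - raw_min) / (raw_max - raw_min)))
    else:
        likelihood = 1.0
    core_ok, plus1, _ = check_constraints(
        window,
        "core",
        matrix.constrained_offsets,
        matrix.preference_offsets,
    )
    return SiteScore(raw_logodds=raw, likelihood=likelihood, core_ok=core_ok, plus1_hydrophobic=plus1)


def load_training_windows(path: str | Path, offsets: Sequence[int] | None = None) -> list[MotifWindow]:
    """Read training windows from a TSV with columns
    ``protein_id  site_position  window``."""
    windows: list[MotifWindow] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("protein_id"):
            continue
        _, _, residues = line.split("\t")
        windows.append(MotifWindow.from_string(residues, offsets))
    return windows


def default_training_windows() -> list[MotifWindow]:
    """Packaged default training set (synthetic stand-in).

    The five in-vivo substrate site classes that motivate the motif (Fpk1,
    Fpk2, Orm1, Orm2, Gpd1 sites) are known, but their full sequence
    contexts are not shipped with this package; the packaged windows are a
    constructed stand-in encoding the published consensus (invariant Arg at
    -5/-3, S/T acceptor, mostly hydrophobic +1) and are labelled synthetic.
    """
    from importlib.resources import files

    path = files("ypkscreen.data").joinpath("training_windows_synthetic.tsv")
    return load_training_windows(str(path), offsets=DEFAULT_OFFSETS)
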