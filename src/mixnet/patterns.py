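"""Binary pattern sets, the overlap observable, and pattern utilities.

Patterns are vectors of N spins, each exactly +1 or -1.  A network stores
P such patterns, either as independent fixed points (associative memory,
role ``AM``) or as an ordered sequence traversed by a cyclic attractor
(sequential pattern recognition, role ``SPR``).  The overlap

    m(sigma, xi) = (1/N) sum_i sigma_i xi_i

is the macroscopic observable used throughout: m = 1 means perfect recall,
m = -1 the specular (anti-pattern) copy, and m = O(N^-1/2) means the state
and the pattern are uncorrelated.  A state with overlap m agrees with the
pattern on a fraction (1 + m)/2 of its neurons.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatternRole",
    "PatternSet",
    "NetworkState",
    "generate_random_patterns",
    "overlap",
    "match_fraction",
    "corrupt",
    "glyph_fixture",
    "glyph_bitmaps",
    "decode_glyph",
    "write_patterns",
    "read_patterns",
]


class PatternRole(str, enum.Enum):
    """What a pattern set is used for: fixed points (AM) or a sequence (SPR)."""

    AM = "AM"
    SPR = "SPR"


def _check_spins(arr: np.ndarray) -> None:
    if not np.all(np.abs(arr) == 1):
        raise ValueError("spin entries must be exactly +1 or -1")


@dataclass
class PatternSet:
    """P x N matrix of +/-1 spins with a role tag and the seed that made it."""

    entries: np.ndarray
    role: PatternRole = PatternRole.AM
    seed: int = 0

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        if self.entries.ndim != 2:
            raise ValueError("entries must be a P x N matrix")
        p, n = self.entries.shape
        if p < 1 or n < 1:
            raise ValueError("need P >= 1 patterns of N >= 1 spins")
        _check_spins(self.entries)
        self.entries = self.entries.astype(np.int8, copy=False)
        self.role = PatternRole(self.role)

    @property
    def n_patterns(self) -> int:
        return self.entries.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.entries.shape[1]

    def __getitem__(self, mu: int) -> np.ndarray:
        return self.entries[mu]


@dataclass
class NetworkState:
    """Instantaneous +/-1 state of all N neurons at a given time step."""

    spins: np.ndarray
    time_index: int = 0

    def __post_init__(self) -> None:
        self.spins = np.asarray(self.spins)
        if self.spins.ndim != 1:
            raise ValueError("spins must be a length-N vector")
        _check_spins(self.spins)
        self.spins = self.spins.astype(np.int8, copy=False)
        if self.time_index < 0:
            raise ValueError("time_index must be >= 0")

    @property
    def n_neurons(self) -> int:
        return self.spins.shape[0]


def generate_random_patterns(
    n_neurons: int,
    n_patterns: int,
    role: PatternRole | str = PatternRole.AM,
    seed: int = 0,
) -> PatternSet:
    """Draw ``n_patterns`` independent patterns of equiprobable +/-1 spins."""
    if n_neurons < 1 or n_patterns < 1:
        raise ValueError("n_neurons and n_patterns must both be >= 1")
    rng = np.random.default_rng(seed)
    entries = rng.choice(np.array([-1, 1], dtype=np.int8), size=(n_patterns, n_neurons))
    return PatternSet(entries=entries, role=PatternRole(role), seed=seed)


def overlap(state, pattern) -> float:
    """Normalized dot product (1/N) sum_i state_i pattern_i, in [-1, 1]."""
    s = state.spins if isinstance(state, NetworkState) else np.asarray(state)
    p = np.asarray(pattern)
    if s.shape != p.shape:
        raise ValueError(f"length mismatch: state {s.shape} vs pattern {p.shape}")
    return float(np.dot(s.astype(np.float64), p.astype(np.float64)) / s.size)


def match_fraction(m: float) -> float:
    """Fraction of neurons agreeing with the pattern for a given overlap m."""
    return (1.0 + m) / 2.0


def corrupt(pattern, flip_fraction: float, seed: int = 0) -> NetworkState:
    """Flip exactly round(flip_fraction * N) spins at random distinct positions.

    The flip count is deterministic (round half up), so the overlap of the
    corrupted state with the original pattern is exactly 1 - 2 * k/N where
    k is the number of flips.
    """
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip_fraction must lie in [0, 1]")
    p = np.asarray(pattern).astype(np.int8, copy=True)
    n = p.size
    n_flips = int(np.floor(flip_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_flips, replace=False)
    p[idx] *= -1
    return NetworkState(spins=p, time_index=0)


# ---------------------------------------------------------------------------
# Procedural glyph fixture
#
# Emulates storing digitized grayscale glyph images: each pixel's intensity
# (bit_depth bits) is encoded as bit_depth spins, most-significant bit first,
# bit value 1 -> +1.  Glyphs are drawn procedurally (seven-segment strokes on
# a per-glyph textured background), so the fixture needs no image assets and
# is reproducible from its seed.  The texture also decorrelates the bit
# planes across glyphs so that distinct patterns are far from one another.
# ---------------------------------------------------------------------------

_SEGMENTS = {  # seven-segment truth table for digits 0-9
    0: "abcdef", 1: "bc", 2: "abged", 3: "abgcd", 4: "fgbc",
    5: "afgcd", 6: "afgedc", 7: "abc", 8: "abcdefg", 9: "abfgcd",
}


def _draw_glyph(width: int, height: int, digit: int, rng: np.random.Generator,
                levels: int) -> np.ndarray:
    """Render one seven-segment digit on a textured background."""
    lo = max(1, levels // 3)
    img = rng.integers(0, lo, size=(height, width))
    fg_lo = (2 * levels) // 3
    x0, x1 = 1, max(2, width - 2)
    y0, ym, y1 = 1, height // 2, max(2, height - 2)
    t = max(1, height // 8)  # stroke thickness

    def hseg(y):
        img[y:y + t, x0:x1 + 1] = rng.integers(fg_lo, levels, size=(min(t, height - y), x1 + 1 - x0))

    def vseg(x, ya, yb):
        img[ya:yb + 1, x:x + t] = rng.integers(fg_lo, levels, size=(yb + 1 - ya, min(t, width - x)))

    segs = _SEGMENTS[digit % 10]
    if "a" in segs:
        hseg(y0)
    if "g" in segs:
        hseg(ym)
    if "d" in segs:
        hseg(y1 - t + 1)
    if "f" in segs:
        vseg(x0, y0, ym)
    if "b" in segs:
        vseg(x1 - t + 1, y0, ym)
    if "e" in segs:
        vseg(x0, ym, y1)
    if "c" in segs:
        vseg(x1 - t + 1, ym, y1)
    return img


def glyph_bitmaps(n_patterns: int, width: int = 16, height: int = 10,
                  bit_depth: int = 8, seed: int = 0) -> np.ndarray:
    """The drawn grayscale bitmaps, shape (P, height, width), values < 2**bit_depth."""
    if bit_depth < 1:
        raise ValueError("bit_depth must be >= 1")
    if width < 3 or height < 3:
        raise ValueError(f"degenerate image size {width}x{height}")
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    rng = np.random.default_rng(seed)
    levels = 2 ** bit_depth
    return np.stack([
        _draw_glyph(width, height, k, rng, levels) for k in range(n_patterns)
    ])


def _encode_bits(imgs: np.ndarray, bit_depth: int) -> np.ndarray:
    flat = imgs.reshape(imgs.shape[0], -1)
    shifts = np.arange(bit_depth - 1, -1, -1)  # MSB first
    bits = (flat[:, :, None] >> shifts[None, None, :]) & 1
    return (2 * bits - 1).reshape(imgs.shape[0], -1).astype(np.int8)


def glyph_fixture(n_patterns: int, width: int = 16, height: int = 10,
                  bit_depth: int = 8, seed: int = 0,
                  role: PatternRole | str = PatternRole.AM) -> PatternSet:
    """Pattern set of encoded glyph bitmaps; N = width * height * bit_depth."""
    imgs = glyph_bitmaps(n_patterns, width, height, bit_depth, seed)
    return PatternSet(entries=_encode_bits(imgs, bit_depth),
                      role=PatternRole(role), seed=seed)


def decode_glyph(spins: np.ndarray, width: int, height: int,
                 bit_depth: int) -> np.ndarray:
    """Invert the bit-to-spin encoding, recovering the grayscale bitmap."""
    bits = (np.asarray(spins).reshape(height, width, bit_depth) + 1) // 2
    shifts = np.arange(bit_depth - 1, -1, -1)
    return np.sum(bits * (1 << shifts)[None, None, :], axis=-1)


# ---------------------------------------------------------------------------
# Plain-text pattern file format: header "N P role", then P lines of N
# space-separated +1/-1 tokens.  Round-trips bit-exactly.
# ---------------------------------------------------------------------------

def write_patterns(patterns: PatternSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{patterns.n_neurons} {patterns.n_patterns} {patterns.role.value}\n")
        for row in patterns.entries:
            fh.write(" ".join(f"{int(v):+d}" for v in row) + "\n")


def read_patterns(path) -> PatternSet:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise ValueError("pattern file header must be 'N P role'")
        n, p, role = int(header[0]), int(header[1]), header[2]
        entries = np.loadtxt(fh, dtype=np.int8, ndmin=2)
    if entries.shape != (p, n):
        raise ValueError(f"pattern file body {entries.shape} does not match header ({p}, {n})")
    return PatternSet(entries=entries, role=PatternRole(role))
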