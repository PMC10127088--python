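"""Physicochemical feature encoders for uridine-centered RNA windows.

Four classical encoders turn a fixed-length ACGU window into a numeric
feature vector:

* **Kmer** — occurrence frequencies of all length-k substrings, in
  lexicographic order.  By default each frequency is the count divided by
  the number of k-mer positions (L - k + 1), so the block sums to 1; the
  sequence-length denominator used by some toolkits is available via
  ``denominator="length"``.
* **ENAC** (enhanced nucleic acid composition) — mononucleotide
  frequencies inside a window of fixed length (default 5) sliding 5'→3',
  one 4-block per window position.
* **CKSNAP** (composition of k-spaced nucleic acid pairs) — frequencies
  of ordered nucleotide pairs separated by k intervening bases, for each
  gap k = 0..k_max, each gap normalized by its pair count L - (k + 1).
* **PseDNC** (pseudo dinucleotide composition) — the 16 dinucleotide
  frequencies augmented with lambda sequence-order correlation factors
  built from squared differences of standardized dinucleotide
  physicochemical indices (rise, roll, shift, slide, tilt, twist), the
  whole vector normalized to sum 1 with tail weight w.

All encoders are pure functions of the sequence and accept either an
:class:`~m5u.windows.RnaWindow` or a plain string.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .windows import RnaWindow, WindowSet

NUCLEOTIDES = "ACGU"
#: the 16 ordered dinucleotides AA, AC, ..., UU in lexicographic order
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
PROPERTY_INDEX_NAMES = ("rise", "roll", "shift", "slide", "tilt", "twist")

SeqLike = Union[str, RnaWindow]


def _seq(x: SeqLike) -> str:
    return x.seq if isinstance(x, RnaWindow) else x


def kmers(k: int) -> list[str]:
    """All 4^k k-mers over ACGU in lexicographic order."""
    return ["".join(p) for p in product(NUCLEOTIDES, repeat=k)]


@dataclass
class FeatureVector:
    """Named, ordered numeric features with a view tag."""

    names: list[str]
    values: np.ndarray
    view: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError(
                f"{len(self.names)} names but {len(self.values)} values"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique within a vector")

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    @staticmethod
    def concat(parts: Sequence["FeatureVector"], view: str = "fused") -> "FeatureVector":
        names = [n for p in parts for n in p.names]
        values = np.concatenate([p.values for p in parts]) if parts else np.array([])
        return FeatureVector(names, values, view)


class PropertyTableError(ValueError):
    pass


@dataclass
class PropertyTable:
    """6 x 16 dinucleotide physicochemical index matrix.

    Rows are the six indices (rise, roll, shift, slide, tilt, twist),
    columns the 16 dinucleotides in lexicographic order.  PseDNC requires
    a standardized table (each row mean 0, sd 1 across the 16 values) so
    that the correlation function is scale-free.
    """

    index_names: tuple[str, ...]
    matrix: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.index_names), 16):
            raise PropertyTableError(
                f"matrix shape {self.matrix.shape} != ({len(self.index_names)}, 16)"
            )
        if self.standardized:
            mean = self.matrix.mean(axis=1)
            sd = self.matrix.std(axis=1)
            if not (np.all(np.abs(mean) < 1e-9) and np.all(np.abs(sd - 1) < 1e-9)):
                raise PropertyTableError("table flagged standardized but is not")

    @property
    def n_indices(self) -> int:
        return len(self.index_names)

    def standardize(self) -> "PropertyTable":
        """Return a copy with each index row at mean 0, sd 1 (population sd)."""
        m = self.matrix
        sd = m.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise PropertyTableError("cannot standardize a constant index row")
        z = (m - m.mean(axis=1, keepdims=True)) / sd
        return PropertyTable(self.index_names, z, standardized=True)

    def value(self, index: int, dinuc: str) -> float:
        return float(self.matrix[index, DINUCLEOTIDES.index(dinuc)])

    @classmethod
    def from_tsv(cls, path: str | Path, standardize: bool = True) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(DINUCLEOTIDES) - set(df.columns)
        if missing:
            raise PropertyTableError(f"missing dinucleotide columns {sorted(missing)}")
        mat = df[list(DINUCLEOTIDES)].to_numpy(dtype=float)
        table = cls(tuple(df.index), mat, standardized=False)
        return table.standardize() if standardize else table

    @classmethod
    def default(cls) -> "PropertyTable":
        """The bundled six-index RNA base-step table, standardized."""
        ref = importlib.resources.files("m5u.data") / "rna_dinucleotide_properties.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path, standardize=True)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=list(self.index_names), columns=list(DINUCLEOTIDES)
        ).rename_axis("index").to_csv(path, sep="\t")


@dataclass(frozen=True)
class PseDncConfig:
    """PseDNC hyperparameters: highest correlation rank lambda and tail weight w."""

    lam: int = 3
    w: float = 0.5

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lambda {self.lam} must be >= 0")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"weight w {self.w} outside [0, 1]")


def encode_kmer(
    win: SeqLike, k: int, denominator: str = "positions"
) -> FeatureVector:
    """k-mer occurrence frequencies in lexicographic order (length 4^k).

    ``denominator="positions"`` divides counts by L - k + 1 (block sums to
    1); ``"length"`` divides by the sequence length L.
    """
    seq = _seq(win)
    L = len(seq)
    if not 1 <= k <= L:
        raise ValueError(f"k={k} outside [1, {L}]")
    if denominator not in ("positions", "length"):
        raise ValueError(f"unknown denominator {denominator!r}")
    counts = {m: 0 for m in kmers(k)}
    for i in range(L - k + 1):
        counts[seq[i : i + k]] += 1
    denom = (L - k + 1) if denominator == "positions" else L
    names = [f"kmer{k}_{m}" for m in counts]
    return FeatureVector(names, np.array(list(counts.values())) / denom, "kmer")


def encode_enac(win: SeqLike, window_len: int = 5) -> FeatureVector:
    """Sliding-window mononucleotide frequencies, 5'→3'.

    One 4-block per start position, 4 * (L - window_len + 1) features
    total (148 for L=41, window_len=5).  Names carry the 1-based window
    start: ``enac_w01_A`` ... .
    """
    seq = _seq(win)
    L = len(seq)
    if not 1 <= window_len <= L:
        raise ValueError(f"window_len={window_len} outside [1, {L}]")
    names: list[str] = []
    values: list[float] = []
    for start in range(L - window_len + 1):
        chunk = seq[start : start + window_len]
        for nt in NUCLEOTIDES:
            names.append(f"enac_w{start + 1:02d}_{nt}")
            values.append(chunk.count(nt) / window_len)
    return FeatureVector(names, np.array(values), "enac")


def encode_cksnap(win: SeqLike, k_max: int = 5) -> FeatureVector:
    """Composition of k-spaced nucleotide pairs for gaps k = 0..k_max.

    For gap k, pair (x, y) counts positions i with seq[i] = x and
    seq[i + k + 1] = y, normalized by the number of such positions
    L - (k + 1).  16 * (k_max + 1) features (96 for k_max=5).
    """
    seq = _seq(win)
    L = len(seq)
    if k_max < 0 or k_max > L - 2:
        raise ValueError(f"k_max={k_max} outside [0, {L - 2}]")
    names: list[str] = []
    values: list[float] = []
    for k in range(k_max + 1):
        counts = {p: 0 for p in DINUCLEOTIDES}
        n_total = L - (k + 1)
        for i in range(n_total):
            counts[seq[i] + seq[i + k + 1]] += 1
        for pair, c in counts.items():
            names.append(f"cksnap_g{k}_{pair}")
            values.append(c / n_total)
    return FeatureVector(names, np.array(values), "cksnap")


def encode_psednc(
    win: SeqLike,
    cfg: PseDncConfig = PseDncConfig(),
    table: Optional[PropertyTable] = None,
) -> FeatureVector:
    """Pseudo dinucleotide composition: 16 + lambda features summing to 1.

    The first 16 components are dinucleotide frequencies and the tail the
    weighted tier-correlation factors theta_j, where theta_j averages the
    correlation function Theta over all position pairs j apart and Theta
    is the mean squared difference of the six standardized property
    indices between two dinucleotides.
    """
    seq = _seq(win)
    L = len(seq)
    if table is None:
        table = PropertyTable.default()
    if not table.standardized:
        raise PropertyTableError("PseDNC requires a standardized property table")
    if cfg.lam > L - 2:
        raise ValueError(f"lambda={cfg.lam} exceeds L-2={L - 2}")

    dinucs = [seq[i : i + 2] for i in range(L - 1)]
    col = {d: j for j, d in enumerate(DINUCLEOTIDES)}
    profile = table.matrix[:, [col[d] for d in dinucs]]  # 6 x (L-1)

    freq = np.array([dinucs.count(d) for d in DINUCLEOTIDES], dtype=float)
    f = freq / freq.sum()  # normalized dinucleotide frequencies, sum 1

    thetas = np.empty(cfg.lam)
    for j in range(1, cfg.lam + 1):
        diffs = profile[:, : L - 1 - j] - profile[:, j:]
        # Theta(a, b) = mean over the six indices of squared value difference
        thetas[j - 1] = np.mean(diffs**2, axis=0).mean() if L - 1 - j > 0 else 0.0

    denom = f.sum() + cfg.w * thetas.sum()
    values = np.concatenate([f / denom, cfg.w * thetas / denom])
    names = [f"psednc_{i}" for i in range(1, 17 + cfg.lam)]
    return FeatureVector(names, values, "psednc")


@dataclass
class PhyschemParams:
    """Hyperparameters of the fused physicochemical view."""

    kmer_ks: tuple[int, ...] = (1, 2, 3)
    kmer_denominator: str = "positions"
    enac_window: int = 5
    cksnap_kmax: int = 5
    psednc: PseDncConfig = field(default_factory=PseDncConfig)
    property_table: Optional[PropertyTable] = None


def encode_physchem(win: SeqLike, params: Optional[PhyschemParams] = None) -> FeatureVector:
    """Fused physicochemical vector, concatenated CKSNAP, ENAC, Kmer, PseDNC."""
    if params is None:
        params = PhyschemParams()
    table = params.property_table or PropertyTable.default()
    parts = [encode_cksnap(win, params.cksnap_kmax), encode_enac(win, params.enac_window)]
    for k in params.kmer_ks:
        parts.append(encode_kmer(win, k, params.kmer_denominator))
    parts.append(encode_psednc(win, params.psednc, table))
    return FeatureVector.concat(parts, view="physchem")


def encode_matrix(
    ws: WindowSet, encoder=encode_physchem, **kwargs
) -> pd.DataFrame:
    """Apply an encoder to every window; rows indexed by window id."""
    rows = [encoder(w, **kwargs) for w in ws]
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(
        np.vstack([r.values for r in rows]),
        index=[w.id for w in ws],
        columns=rows[0].names,
    )
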