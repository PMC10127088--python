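"""Fixed-length RNA windows centered on candidate uridine sites.

Site-centered classification of RNA modifications operates on short
sequence windows: a candidate uridine plus an equal number of flanking
nucleotides on each side (41 nt total with the default flank of 20).
This module reads and writes such windows as FASTA, extracts them from
longer transcripts, and generates labeled synthetic window sets with a
plantable consensus motif for testing and calibration.

Window-internal coordinates are signed, with the candidate site at 0 and
flanks at -flank ... +flank.  Transcript coordinates are 1-based, fully
closed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGU")
#: characters accepted on input; T is silently mapped to U
INPUT_ALPHABET = frozenset("ACGUT")

Label = Literal["positive", "negative", "unlabeled"]

DEFAULT_WINDOW_LENGTH = 41


class WindowError(ValueError):
    """Raised when a window violates the fixed-length centered-U contract."""


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and map DNA T to RNA U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaWindow:
    """One fixed-length ACGU window centered on a candidate U.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA record id or generated name).
    seq : str
        Sequence over {A, C, G, U}; odd length; the center character must
        be ``U`` (the candidate site).
    label : {"positive", "negative", "unlabeled"}
        Class label: positive = modified site, negative = unmodified U.
    source_pos : int, optional
        1-based coordinate of the center on the source transcript.
    """

    id: str
    seq: str
    label: Label = "unlabeled"
    source_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.seq) % 2 == 0:
            raise WindowError(
                f"window {self.id!r}: length {len(self.seq)} is even; "
                "windows must have odd length so a center exists"
            )
        bad = set(self.seq) - ALPHABET
        if bad:
            raise WindowError(
                f"window {self.id!r}: invalid character(s) {sorted(bad)!r}; "
                "only A, C, G, U are allowed"
            )
        center = self.seq[len(self.seq) // 2]
        if center != "U":
            raise WindowError(
                f"window {self.id!r}: center character is {center!r}, expected 'U'"
            )
        if self.label not in ("positive", "negative", "unlabeled"):
            raise WindowError(f"window {self.id!r}: unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def flank(self) -> int:
        return len(self.seq) // 2

    def at(self, offset: int) -> str:
        """Nucleotide at a signed window position (0 = candidate site)."""
        idx = self.flank + offset
        if not 0 <= idx < len(self.seq):
            raise IndexError(f"offset {offset} outside -{self.flank}..+{self.flank}")
        return self.seq[idx]


@dataclass
class WindowSet:
    """An ordered collection of same-length windows with unique ids."""

    windows: list[RnaWindow] = field(default_factory=list)
    mode_tag: str = ""

    def __post_init__(self) -> None:
        lengths = {len(w) for w in self.windows}
        if len(lengths) > 1:
            raise WindowError(f"mixed window lengths {sorted(lengths)}")
        ids = [w.id for w in self.windows]
        if len(set(ids)) != len(ids):
            seen, dupes = set(), set()
            for i in ids:
                (dupes if i in seen else seen).add(i)
            raise WindowError(f"duplicate window ids: {sorted(dupes)[:5]}")

    @property
    def L(self) -> int:
        if not self.windows:
            raise WindowError("empty WindowSet has no window length")
        return len(self.windows[0])

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[RnaWindow]:
        return iter(self.windows)

    def __getitem__(self, i: int) -> RnaWindow:
        return self.windows[i]

    def labels(self) -> np.ndarray:
        """0/1 array (positive=1, negative=0); errors on unlabeled windows."""
        out = np.empty(len(self.windows), dtype=int)
        for i, w in enumerate(self.windows):
            if w.label == "unlabeled":
                raise WindowError(f"window {w.id!r} is unlabeled")
            out[i] = 1 if w.label == "positive" else 0
        return out

    def sequences(self) -> list[str]:
        return [w.seq for w in self.windows]

    def subset(self, label: Label) -> "WindowSet":
        return WindowSet([w for w in self.windows if w.label == label], self.mode_tag)

    def __add__(self, other: "WindowSet") -> "WindowSet":
        return WindowSet(self.windows + other.windows, self.mode_tag or other.mode_tag)


def read_fasta(
    path: str | Path,
    label: Label = "unlabeled",
    expected_length: Optional[int] = DEFAULT_WINDOW_LENGTH,
    mode_tag: str = "",
) -> WindowSet:
    """Read window sequences from a FASTA file.

    Sequences are uppercased and T is mapped to U; any other non-ACGU
    character is a hard error (ambiguity codes are not representable in
    the downstream encoders).  Record order is preserved.

    Parameters
    ----------
    expected_length : int or None
        Required window length (default 41).  ``None`` accepts any odd
        length, provided all records agree.
    """
    windows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        bad = set(raw) - INPUT_ALPHABET
        if bad:
            raise WindowError(
                f"record {rec.id!r}: invalid character(s) {sorted(bad)!r}"
            )
        seq = normalize_rna(raw)
        if expected_length is not None and len(seq) != expected_length:
            raise WindowError(
                f"record {rec.id!r}: length {len(seq)} != expected {expected_length}"
            )
        windows.append(RnaWindow(id=rec.id, seq=seq, label=label))
    return WindowSet(windows, mode_tag=mode_tag)


def write_fasta(ws: WindowSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(w.seq), id=w.id, description=w.label) for w in ws
    ]
    SeqIO.write(records, str(path), "fasta")


def apply_labels(ws: WindowSet, sheet_path: str | Path) -> WindowSet:
    """Relabel a WindowSet from a TSV label sheet with columns id, label."""
    labels: dict[str, str] = {}
    with open(sheet_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"id", "label"} <= set(reader.fieldnames):
            raise WindowError("label sheet must have columns 'id' and 'label'")
        for row in reader:
            labels[row["id"]] = row["label"]
    out = []
    for w in ws:
        lab = labels.get(w.id, w.label)
        out.append(RnaWindow(w.id, w.seq, lab, w.source_pos))  # type: ignore[arg-type]
    return WindowSet(out, ws.mode_tag)


def extract_window(
    transcript: str,
    pos: int,
    flank: int = 20,
    id: Optional[str] = None,
    label: Label = "unlabeled",
) -> RnaWindow:
    """Extract the window centered at a 1-based transcript position.

    The site must be a U (after T->U mapping) and both flanks must fit
    inside the transcript; windows are never padded.
    """
    seq = normalize_rna(transcript)
    if not 1 <= pos <= len(seq):
        raise WindowError(f"position {pos} outside transcript of length {len(seq)}")
    if seq[pos - 1] != "U":
        raise WindowError(
            f"position {pos} is {seq[pos - 1]!r}, not a uridine site"
        )
    if pos - flank < 1 or pos + flank > len(seq):
        raise WindowError(
            f"window [{pos - flank}, {pos + flank}] exceeds transcript "
            f"bounds [1, {len(seq)}]; no padding is applied"
        )
    window = seq[pos - flank - 1 : pos + flank]
    return RnaWindow(
        id=id if id is not None else f"pos{pos}",
        seq=window,
        label=label,
        source_pos=pos,
    )


def generate_synthetic(
    n_pos: int,
    n_neg: int,
    L: int = DEFAULT_WINDOW_LENGTH,
    motif: str = "UUC",
    motif_offset: int = 0,
    motif_prob: float = 1.0,
    seed: int = 0,
) -> WindowSet:
    """Generate a labeled synthetic window set with a plantable motif.

    Positives carry ``motif`` starting at signed position ``motif_offset``
    (0 = the candidate site) with probability ``motif_prob``; all other
    positions, and negatives entirely, are uniform over {A, C, G, U}.
    Every center is forced to U, emulating uridine-centered windows.
    Fully reproducible from ``seed``.
    """
    if L % 2 == 0:
        raise WindowError(f"window length {L} must be odd")
    center = L // 2
    bad = set(motif) - ALPHABET
    if bad:
        raise WindowError(f"motif contains non-ACGU character(s) {sorted(bad)!r}")
    start = center + motif_offset
    if start < 0 or start + len(motif) > L:
        raise WindowError(
            f"motif at offset {motif_offset} does not fit inside window of length {L}"
        )
    if not 0.0 <= motif_prob <= 1.0:
        raise WindowError(f"motif_prob {motif_prob} outside [0, 1]")

    rng = np.random.default_rng(seed)
    nts = np.array(list("ACGU"))
    windows = []

    def draw(label: Label, idx: int, plant: bool) -> RnaWindow:
        chars = nts[rng.integers(0, 4, size=L)]
        chars[center] = "U"
        if plant:
            for j, m in enumerate(motif):
                chars[start + j] = m
            chars[center] = "U"  # motif may not cover the center; keep it U
        return RnaWindow(id=f"{label[:3]}_{idx}", seq="".join(chars), label=label)

    for i in range(n_pos):
        windows.append(draw("positive", i, rng.random() < motif_prob))
    for i in range(n_neg):
        windows.append(draw("negative", i, False))
    return WindowSet(windows, mode_tag="synthetic")
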