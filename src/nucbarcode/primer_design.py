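"""Primer-pair design from a conservation profile.

A primer window is 20 consecutive alignment columns in which every column is
highly conserved (majority fraction at or above a threshold, default 0.90)
and essentially gap-free. Windows are paired whenever the implied amplicon —
measured primer-inclusive, from the start of the upstream window to the end
of the downstream one — falls in the design range of 100-350 bp. The forward
primer is the strict consensus of the upstream window; the reverse primer is
the reverse complement of the downstream window's consensus. Pairs are named
``<seed_label>-<triplet>`` with a base-26 counter starting at "aaa", mirroring
names like 23579-aaa.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .alignment_profile import ConservationProfile, consensus_sequence
from .core_io import SeqRecord, reverse_complement, write_fasta

WINDOW_LENGTH = 20
NAME_RE = re.compile(r"^[^-]+(-[^-]+)*-[a-z]{3}$")


@dataclass
class PrimerWindow:
    """A 20-column conserved window of an alignment profile."""

    column_interval: tuple[int, int]
    min_column_conservation: float
    max_gap_fraction: float
    consensus_20mer: str

    @property
    def start(self) -> int:
        return self.column_interval[0]

    @property
    def end(self) -> int:
        return self.column_interval[1]


@dataclass
class PrimerPair:
    """A named forward/reverse 20-mer pair with its design window provenance."""

    name: str
    forward: str
    reverse: str
    amplicon_min: int = 100
    amplicon_max: int = 350
    upstream: PrimerWindow | None = None
    downstream: PrimerWindow | None = None

    @property
    def implied_amplicon(self) -> int | None:
        if self.upstream is None or self.downstream is None:
            return None
        return self.downstream.end - self.upstream.start


def triplet_name(index: int) -> str:
    """Base-26 lowercase triplet: 0 -> 'aaa', 1 -> 'aab', 26 -> 'aba'."""
    if not 0 <= index < 26 ** 3:
        raise ValueError(f"triplet index {index} out of range [0, 17576)")
    chars = []
    for _ in range(3):
        chars.append(chr(ord("a") + index % 26))
        index //= 26
    return "".join(reversed(chars))


def triplet_index(name: str) -> int:
    """Inverse of :func:`triplet_name`."""
    if len(name) != 3 or not name.islower() or not name.isalpha():
        raise ValueError(f"not a lowercase triplet: {name!r}")
    index = 0
    for ch in name:
        index = index * 26 + (ord(ch) - ord("a"))
    return index


def find_conserved_windows(profile: ConservationProfile,
                           window: int = WINDOW_LENGTH,
                           min_conservation: float = 0.90,
                           max_gap_fraction: float = 0.0) -> list[PrimerWindow]:
    """All window-length column intervals whose every column satisfies the
    conservation and gap thresholds, in ascending start order."""
    n = len(profile)
    out: list[PrimerWindow] = []
    for start in range(0, n - window + 1):
        cols = slice(start, start + window)
        maj = profile.majority_fraction[cols]
        gaps = profile.gap_fraction[cols]
        if (maj >= min_conservation).all() and (gaps <= max_gap_fraction).all():
            out.append(PrimerWindow(
                (start, start + window),
                float(maj.min()),
                float(gaps.max()),
                consensus_sequence(profile, "strict",
                                   columns=(start, start + window)),
            ))
    return out


def enumerate_primer_pairs(windows: list[PrimerWindow],
                           profile: ConservationProfile,
                           seed_label: str,
                           amplicon_range: tuple[int, int] = (100, 350),
                           ) -> list[PrimerPair]:
    """Pair every upstream window with every non-overlapping downstream
    window whose implied (primer-inclusive) amplicon is in range.

    Pairs are ordered by (upstream start, downstream start) and named with
    consecutive triplets from "aaa".
    """
    amp_min, amp_max = amplicon_range
    pairs: list[PrimerPair] = []
    for up in windows:
        for down in windows:
            if down.start < up.end:  # overlapping or upstream of up
                continue
            implied = down.end - up.start
            if not amp_min <= implied <= amp_max:
                continue
            name = f"{seed_label}-{triplet_name(len(pairs))}"
            pairs.append(PrimerPair(
                name=name,
                forward=up.consensus_20mer,
                reverse=reverse_complement(down.consensus_20mer),
                amplicon_min=amp_min,
                amplicon_max=amp_max,
                upstream=up,
                downstream=down,
            ))
    return pairs


def design_primers(profile: ConservationProfile, seed_label: str,
                   min_conservation: float = 0.90,
                   max_gap_fraction: float = 0.0,
                   amplicon_range: tuple[int, int] = (100, 350),
                   ) -> list[PrimerPair]:
    """Convenience: window scan followed by pair enumeration."""
    windows = find_conserved_windows(profile,
                                     min_conservation=min_conservation,
                                     max_gap_fraction=max_gap_fraction)
    return enumerate_primer_pairs(windows, profile, seed_label, amplicon_range)


def write_pairs_tsv(pairs: list[PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tforward\treverse\tamplicon_min\tamplicon_max\t"
                 "upstream_start\tdownstream_start\n")
        for p in pairs:
            up = p.upstream.start if p.upstream else ""
            down = p.downstream.start if p.downstream else ""
            fh.write(f"{p.name}\t{p.forward}\t{p.reverse}\t{p.amplicon_min}\t"
                     f"{p.amplicon_max}\t{up}\t{down}\n")


def write_pairs_fasta(pairs: list[PrimerPair], path: str | Path) -> None:
    records = []
    for p in pairs:
        records.append(SeqRecord(f"{p.name}-F", p.forward))
        records.append(SeqRecord(f"{p.name}-R", p.reverse))
    write_fasta(records, path)


def read_pairs_tsv(path: str | Path) -> list[PrimerPair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3 or not f[0]:
                continue
            pairs.append(PrimerPair(
                name=f[col["name"]],
                forward=f[col["forward"]],
                reverse=f[col["reverse"]],
                amplicon_min=int(f[col["amplicon_min"]]) if f[col["amplicon_min"]] else 100,
                amplicon_max=int(f[col["amplicon_max"]]) if f[col["amplicon_max"]] else 350,
            ))
    return pairs
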