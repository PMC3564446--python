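"""Flanking-sequence context of identified cysteines.

Windows of five residues up- and downstream of each identified thiol are
extracted (truncated, never padded, at protein termini), residues are
grouped into six physico-chemical types, and each cluster's type frequency
is normalized to the whole window library -- an enrichment ratio of 1 means
the cluster looks like the library.  Clusters are compared by a Pearson
chi-square on the 2 x k contingency of type counts (k = 6 with cysteine,
5 with all cysteines removed; df = k - 1).  The central cysteine itself is
never counted.

The headline biological signal this detects: early-oxidizing thiols tend
to carry additional cysteines within a few residues (C-X-X-C-like motifs
of disulfide oxidoreductases), whereas late collapsers and always-reduced
thiols largely lack nearby cysteines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "AA_TYPE",
    "TYPE_ORDER",
    "SequenceWindow",
    "ChisqResult",
    "aa_type",
    "extract_window",
    "type_counts",
    "enrichment",
    "cluster_chisq",
    "combine_clusters",
    "position_frequency_table",
]

#: Residue -> type mapping.  H counts as positively charged and G as
#: nonpolar; the mapping is replaceable via the ``table`` argument.
AA_TYPE: dict[str, str] = {
    "C": "cysteine",
    "D": "negative", "E": "negative",
    "K": "positive", "R": "positive", "H": "positive",
    "F": "aromatic", "W": "aromatic", "Y": "aromatic",
    "S": "polar", "T": "polar", "N": "polar", "Q": "polar",
    "A": "nonpolar", "V": "nonpolar", "L": "nonpolar", "I": "nonpolar",
    "M": "nonpolar", "P": "nonpolar", "G": "nonpolar",
}

TYPE_ORDER = ("cysteine", "positive", "negative", "polar", "nonpolar", "aromatic")


def aa_type(residue: str, table: Mapping[str, str] | None = None, strict: bool = True) -> str | None:
    """Physico-chemical type of one residue; error (or None) if nonstandard."""
    table = table or AA_TYPE
    t = table.get(residue.upper())
    if t is None:
        if strict:
            raise ValueError(f"nonstandard residue {residue!r}")
        return None
    return t


@dataclass(frozen=True)
class SequenceWindow:
    """Up to 5+1+5 residues centred on an identified cysteine."""

    peptide_id: str
    seq: str
    center: int  # 0-based index of the cysteine within ``seq``
    label: str | None = None

    def __post_init__(self) -> None:
        if self.seq[self.center] != "C":
            raise ValueError("central residue must be C")

    @property
    def length(self) -> int:
        return len(self.seq)

    def flanking_residues(self) -> str:
        return self.seq[: self.center] + self.seq[self.center + 1:]


def extract_window(
    protein_seq: str,
    cys_pos: int,
    flank: int = 5,
    peptide_id: str = "",
    label: str | None = None,
) -> SequenceWindow:
    """Window of ``flank`` residues either side of a cysteine (1-based position).

    Truncated at the protein termini; the recorded length reflects that.
    """
    if not 1 <= cys_pos <= len(protein_seq):
        raise ValueError(f"cys_pos {cys_pos} out of range for length {len(protein_seq)}")
    if protein_seq[cys_pos - 1] != "C":
        raise ValueError(f"residue at position {cys_pos} is {protein_seq[cys_pos - 1]!r}, not C")
    start = max(0, cys_pos - 1 - flank)
    stop = min(len(protein_seq), cys_pos + flank)
    return SequenceWindow(peptide_id, protein_seq[start:stop], cys_pos - 1 - start, label)


def type_counts(
    windows: Iterable[SequenceWindow],
    include_cys: bool = True,
    table: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Residue-type counts over the flanking positions of a window set.

    The central cysteine is always excluded; with ``include_cys=False``
    every cysteine is excluded and only the five non-cysteine types are
    counted.
    """
    types = TYPE_ORDER if include_cys else TYPE_ORDER[1:]
    counts = {t: 0 for t in types}
    for w in windows:
        for res in w.flanking_residues():
            t = aa_type(res, table)
            if t == "cysteine" and not include_cys:
                continue
            counts[t] += 1
    return counts


def enrichment(
    cluster_windows: Sequence[SequenceWindow],
    library_windows: Sequence[SequenceWindow],
    table: Mapping[str, str] | None = None,
) -> dict[str, float | None]:
    """Cluster-vs-library frequency ratio per residue type.

    ratio(type) = freq_in_cluster / freq_in_library, central cysteines
    excluded from both.  A type absent from the library has an undefined
    ratio, reported as None.
    """
    if not cluster_windows:
        raise ValueError("empty cluster")
    cc = type_counts(cluster_windows, table=table)
    lc = type_counts(library_windows, table=table)
    n_c, n_l = sum(cc.values()), sum(lc.values())
    if n_l == 0:
        raise ValueError("empty library")
    out: dict[str, float | None] = {}
    for t in TYPE_ORDER:
        if lc[t] == 0:
            out[t] = None
        else:
            out[t] = (cc[t] / n_c) / (lc[t] / n_l)
    return out


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p: float


def cluster_chisq(
    windows_a: Sequence[SequenceWindow],
    windows_b: Sequence[SequenceWindow],
    include_cys: bool = True,
    table: Mapping[str, str] | None = None,
) -> ChisqResult:
    """Pearson chi-square comparing two clusters' residue-type counts.

    The 2 x k contingency has k = 6 types with cysteine, k = 5 without;
    df = k - 1.  An expected count of zero (a type absent from both
    groups) aborts with guidance rather than returning a spurious value.
    """
    if not windows_a or not windows_b:
        raise ValueError("both window groups must be non-empty")
    ca = type_counts(windows_a, include_cys, table)
    cb = type_counts(windows_b, include_cys, table)
    types = list(ca)
    obs = np.array([[ca[t] for t in types], [cb[t] for t in types]], dtype=float)
    col_zero = obs.sum(axis=0) == 0
    if col_zero.any():
        dead = [t for t, z in zip(types, col_zero) if z]
        raise ValueError(
            f"type(s) {dead} have zero expected count; merge categories before testing"
        )
    stat, p, df, _ = chi2_contingency(obs, correction=False)
    return ChisqResult(float(stat), int(df), float(p))


def combine_clusters(
    windows: Iterable[SequenceWindow],
    merge: Sequence[Sequence[str]] = (("A", "B"), ("D", "E")),
) -> dict[str, list[SequenceWindow]]:
    """Pool windows by (possibly merged) cluster label.

    With the default merge map, A and B pool into "AB" and D and E into
    "DE"; other labels keep their own group.
    """
    merged_name = {lab: "".join(group) for group in merge for lab in group}
    out: dict[str, list[SequenceWindow]] = {}
    for w in windows:
        if w.label is None:
            continue
        out.setdefault(merged_name.get(w.label, w.label), []).append(w)
    return out


def position_frequency_table(
    windows: Sequence[SequenceWindow], flank: int = 5
) -> pd.DataFrame:
    """Per-position residue frequency table (logo data, positions -flank..+flank).

    Frequencies at each offset are over the windows that actually cover
    that offset (terminal truncation shrinks the denominator).
    """
    offsets = list(range(-flank, flank + 1))
    counts: dict[int, dict[str, int]] = {o: {} for o in offsets}
    for w in windows:
        for o in offsets:
            idx = w.center + o
            if 0 <= idx < w.length:
                res = w.seq[idx]
                counts[o][res] = counts[o].get(res, 0) + 1
    residues = sorted({r for per in counts.values() for r in per})
    data = {
        o: {r: per.get(r, 0) / total if (total := sum(per.values())) else 0.0
            for r in residues}
        for o, per in counts.items()
    }
    return pd.DataFrame(data, index=residues).T
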