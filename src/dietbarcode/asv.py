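"""Per-sample reads -> filtered, rarefied ASV count table.

The processing chain is order-fixed and mirrors a standard amplicon
workflow reduced to its defined computations:

1. :func:`dereplicate` — exact-sequence grouping per sample (no error
   model; an error read is its own ASV and is left for the low-frequency
   filter);
2. :func:`remove_chimeras` — per-sample removal of exact two-parent
   bimeras whose parents are at least twice as abundant;
3. :func:`filter_low_frequency` — zero any cell below 1% of its sample
   total (strictly fewer than);
4. :func:`rarefy` — subsample every sample to a fixed depth without
   replacement.

Each stage logs read accounting per sample and never invents new ASVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._util import child_rng

STAGES = ("raw", "nochim", "lowfreq_filtered", "rarefied")


@dataclass
class ASVTable:
    """Sample x ASV count matrix with a stage tag and accounting log.

    ``counts`` is indexed by ASV sequence (rows) with sample-id columns;
    values are non-negative integers.
    """

    counts: pd.DataFrame
    stage: str
    log: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def asvs(self) -> list[str]:
        return list(self.counts.index)

    def sample_total(self, sample: str) -> int:
        return int(self.counts[sample].sum())

    def asv_ids(self) -> dict[str, str]:
        """Stable display ids, ranked by total abundance then sequence."""
        order = sorted(
            self.counts.index, key=lambda s: (-int(self.counts.loc[s].sum()), s)
        )
        return {seq: f"ASV{i + 1:04d}" for i, seq in enumerate(order)}

    def to_tsv(self, path: str | Path) -> None:
        ids = self.asv_ids()
        out = self.counts.copy()
        out.insert(0, "asv_id", [ids[s] for s in out.index])
        out.index.name = "sequence"
        out.to_csv(path, sep="\t")

    def write_fasta(self, path: str | Path) -> None:
        ids = self.asv_ids()
        with open(path, "w") as fh:
            for seq, asv_id in ids.items():
                fh.write(f">{asv_id}\n{seq}\n")


def _sorted_counts(cells: Mapping[str, Mapping[str, int]], samples: Sequence[str]) -> pd.DataFrame:
    # pd.DataFrame({sample: {seq: count}}) is already sequences x samples
    df = pd.DataFrame(cells).reindex(columns=list(samples)).fillna(0).astype(np.int64)
    # deterministic row order: total abundance desc, then sequence
    order = sorted(df.index, key=lambda s: (-int(df.loc[s].sum()), s))
    return df.loc[order]


def dereplicate(reads: Mapping[str, Iterable[str]]) -> ASVTable:
    """Group identical reads per sample into raw ASV counts.

    Reads containing ``N`` (or any non-ACGT character) are excluded and
    counted in the log.  Empty samples are retained as all-zero columns
    with a warning.
    """
    cells: dict[str, dict[str, int]] = {}
    log_rows = []
    for sample, sample_reads in reads.items():
        col: dict[str, int] = cells.setdefault(sample, {})
        n_in = n_bad = 0
        for read in sample_reads:
            n_in += 1
            seq = read.upper()
            if set(seq) - set("ACGT"):
                n_bad += 1
                continue
            col[seq] = col.get(seq, 0) + 1
        if n_in == 0:
            warnings.warn(f"sample {sample} has no reads; retained as zero column")
        log_rows.append({"sample": sample, "input": n_in, "excluded_ambiguous": n_bad})
    counts = _sorted_counts(cells, list(reads))
    return ASVTable(counts=counts, stage="raw", log=pd.DataFrame(log_rows))


class _ParentIndex:
    """Prefix/suffix lookup over candidate chimera parents of one length."""

    def __init__(self, parents: list[str]):
        self.parents = parents
        self.prefixes: list[set[str] | None] = [None] * (len(parents[0]) + 1 if parents else 1)
        self.suffixes: list[set[str] | None] = [None] * (len(parents[0]) + 1 if parents else 1)

    def has_split(self, seq: str) -> bool:
        L = len(seq)
        for k in range(1, L):
            if self.prefixes[k] is None:
                self.prefixes[k] = {p[:k] for p in self.parents}
                self.suffixes[k] = {p[k:] for p in self.parents}
            if seq[:k] in self.prefixes[k] and seq[k:] in self.suffixes[k]:
                # a single parent cannot supply both halves: that parent
                # would equal seq, and parents are strictly more abundant
                return True
        return False


def remove_chimeras(table: ASVTable, min_fold: float = 2.0) -> ASVTable:
    """Per-sample removal of exact bimeras.

    An ASV is removed from a sample iff two parents of the same length
    exist in the same sample, each with at least ``min_fold`` times its
    abundance, whose prefix and suffix compose it exactly at some
    breakpoint.  Parents are necessarily distinct from the candidate
    because they are strictly more abundant.
    """
    counts = table.counts.copy()
    log_rows = []
    for sample in counts.columns:
        col = counts[sample]
        present = {seq: int(c) for seq, c in col[col > 0].items()}
        total_in = sum(present.values())
        max_count = max(present.values(), default=0)
        index_cache: dict[tuple[int, int], _ParentIndex | None] = {}
        removed_reads = 0
        for seq, c in present.items():
            need = min_fold * c
            if need > max_count:
                continue
            key = (int(np.ceil(need)), len(seq))
            if key not in index_cache:
                parents = [
                    p for p, pc in present.items() if pc >= key[0] and len(p) == key[1]
                ]
                index_cache[key] = _ParentIndex(parents) if len(parents) >= 2 else None
            index = index_cache[key]
            if index is not None and index.has_split(seq):
                removed_reads += c
                counts.loc[seq, sample] = 0
        log_rows.append(
            {
                "sample": sample,
                "input": total_in,
                "nonchim": total_in - removed_reads,
                "chimera_removed": removed_reads,
            }
        )
    counts = counts[counts.sum(axis=1) > 0]
    return ASVTable(counts=counts, stage="nochim", log=pd.DataFrame(log_rows))


def filter_low_frequency(table: ASVTable, threshold: float = 0.01) -> ASVTable:
    """Zero cells whose share of the sample total is strictly below threshold.

    The rule is per sample and strict ("fewer than 1.0%"): a count at
    exactly the threshold is retained.  All-zero ASVs are dropped.
    """
    counts = table.counts.copy()
    log_rows = []
    for sample in counts.columns:
        total = int(counts[sample].sum())
        if total == 0:
            log_rows.append({"sample": sample, "input": 0, "lowfreq_removed": 0})
            continue
        frac = counts[sample] / total
        mask = (frac < threshold) & (counts[sample] > 0)
        removed = int(counts.loc[mask, sample].sum())
        counts.loc[mask, sample] = 0
        log_rows.append({"sample": sample, "input": total, "lowfreq_removed": removed})
    counts = counts[counts.sum(axis=1) > 0]
    return ASVTable(counts=counts, stage="lowfreq_filtered", log=pd.DataFrame(log_rows))


def rarefy(table: ASVTable, depth: int = 1000, seed: int = 0) -> ASVTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    kept = {}
    log_rows = []
    for i, sample in enumerate(table.counts.columns):
        col = table.counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample} has {total} < {depth} reads; dropped from rarefied table"
            )
            log_rows.append({"sample": sample, "input": total, "rarefied": 0, "kept": False})
            continue
        if total == depth:
            sub = col
        else:
            rng = child_rng(seed, 3, i)
            sub = rng.multivariate_hypergeometric(col, depth)
        kept[sample] = sub
        log_rows.append({"sample": sample, "input": total, "rarefied": depth, "kept": True})
    counts = pd.DataFrame(kept, index=table.counts.index).astype(np.int64)
    counts = counts[counts.sum(axis=1) > 0]
    return ASVTable(counts=counts, stage="rarefied", log=pd.DataFrame(log_rows))


def rarefaction_curve(counts: Sequence[int], sizes: Sequence[int]) -> np.ndarray:
    """Exact expected ASV richness at each subsample size.

    Hypergeometric closed form, not Monte-Carlo:
    ``E[S_m] = sum_i 1 - C(n - n_i, m) / C(n, m)``.
    """
    n_i = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    n = int(n_i.sum())
    sizes = np.asarray(sizes, dtype=np.int64)
    if np.any(sizes > n):
        raise ValueError("subsample size exceeds sample total")
    if np.any(sizes < 0):
        raise ValueError("subsample sizes must be non-negative")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(sizes), dtype=float)
    for j, m in enumerate(sizes):
        if m == 0:
            out[j] = 0.0
            continue
        keep = (n - n_i) >= m
        absent = np.zeros(len(n_i))
        if keep.any():
            absent[keep] = np.exp(log_comb(n - n_i[keep], m) - log_comb(n, m))
        out[j] = float(np.sum(1.0 - absent))
    return out


def run_chain(
    reads: Mapping[str, Iterable[str]],
    depth: int = 1000,
    lowfreq_threshold: float = 0.01,
    seed: int = 0,
) -> dict[str, ASVTable]:
    """Run the full order-fixed chain, returning every stage."""
    raw = dereplicate(reads)
    nochim = remove_chimeras(raw)
    filtered = filter_low_frequency(nochim, threshold=lowfreq_threshold)
    rarefied = rarefy(filtered, depth=depth, seed=seed)
    return {"raw": raw, "nochim": nochim, "lowfreq_filtered": filtered, "rarefied": rarefied}


def accounting_table(stages: Mapping[str, ASVTable]) -> pd.DataFrame:
    """Merge per-stage logs into one read-accounting table per sample."""
    merged: pd.DataFrame | None = None
    for name in STAGES:
        if name not in stages:
            continue
        log = stages[name].log
        if log.empty:
            continue
        log = log.rename(columns={c: c if c == "sample" else f"{name}_{c}" for c in log.columns})
        merged = log if merged is None else merged.merge(log, on="sample", how="outer")
    return merged if merged is not None else pd.DataFrame()
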