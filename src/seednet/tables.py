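"""CSV export/import of co-occurrence tables and cluster reports.

Column orders are fixed and rows are fully ordered (frequency
descending, then lemma lexicographically for ties), so identical inputs
produce byte-identical files and every writer round-trips through its
reader.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from .cooccurrence import CooccurrenceTable
from .network import ClusterInfo

FREQUENCY_COLUMNS = ("lemma", "count", "n_seed_sentences", "frequency")
PAIR_COLUMNS = ("lemma_a", "lemma_b", "count")
CLUSTER_COLUMNS = ("cluster_id", "rank", "n_nodes", "total_size", "members")


def _open_writer(path: str | Path):
    return open(path, "w", encoding="utf-8", newline="")


def write_frequency_csv(table: CooccurrenceTable, path: str | Path) -> None:
    """Per-lemma seed co-occurrence frequencies (seed lemmas excluded)."""
    rows = sorted(table.freq, key=lambda l: (-table.lemma_totals[l], l))
    with _open_writer(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(FREQUENCY_COLUMNS)
        for lemma in rows:
            count = table.lemma_totals[lemma]
            writer.writerow(
                [lemma, count, table.n_seed_sentences,
                 repr(count / table.n_seed_sentences)]
            )


def read_frequency_csv(path: str | Path) -> CooccurrenceTable:
    """Rebuild a (pairless) table from a frequency CSV."""
    totals: dict[str, int] = {}
    n = 0
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            totals[row["lemma"]] = int(row["count"])
            n = int(row["n_seed_sentences"])
    freq = {lemma: c / n for lemma, c in totals.items()} if n else {}
    return CooccurrenceTable(
        n_seed_sentences=n, freq=freq, pair_counts={}, lemma_totals=totals
    )


def write_pairs_csv(table: CooccurrenceTable, path: str | Path) -> None:
    """Pairwise sentence co-occurrence counts (lexicographic pairs)."""
    with _open_writer(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(PAIR_COLUMNS)
        for a, b in sorted(table.pair_counts):
            writer.writerow([a, b, table.pair_counts[(a, b)]])


def read_pairs_csv(path: str | Path) -> dict[tuple[str, str], int]:
    with open(path, encoding="utf-8", newline="") as fh:
        return {
            (row["lemma_a"], row["lemma_b"]): int(row["count"])
            for row in csv.DictReader(fh)
        }


def write_cluster_report(clusters: Sequence[ClusterInfo], path: str | Path) -> None:
    """Ranked cluster report; members are ';'-joined, size-descending."""
    with _open_writer(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(CLUSTER_COLUMNS)
        for c in clusters:
            writer.writerow(
                [c.cluster_id, c.rank, c.n_nodes, repr(c.total_size),
                 ";".join(c.members)]
            )


def read_cluster_report(path: str | Path) -> list[ClusterInfo]:
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ClusterInfo(
                    cluster_id=int(row["cluster_id"]),
                    rank=int(row["rank"]),
                    n_nodes=int(row["n_nodes"]),
                    total_size=float(row["total_size"]),
                    members=tuple(row["members"].split(";")),
                )
            )
    return out


def write_table(obj: CooccurrenceTable | Sequence[ClusterInfo], path: str | Path) -> None:
    """Dispatching writer: co-occurrence tables and cluster reports."""
    if isinstance(obj, CooccurrenceTable):
        write_frequency_csv(obj, path)
    else:
        write_cluster_report(obj, path)
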