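"""Non-reference L1 insertion calls and de novo vs polymorphic filtering.

A call table (one row per detection of a non-reference L1 junction in one
cell line) is classified with three criteria: a candidate is *de novo* only
if (i) its locus is detected in exactly one of the cell lines analyzed,
(ii) it is absent from the matching parental sample (time point T0 — a T0
detection in either line marks the locus polymorphic for both, since it is
then of germ-line origin), and (iii) it does not fall within a tolerance
window of a known non-reference germ-line insertion from the published
catalog.  Detections in earlier hiPSC passages count toward a line's
detection but not toward T0 absence.

Positions are 1-based in tables and files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TIME_POINTS",
    "InsertionCall",
    "KnownInsertionCatalog",
    "classify_calls",
    "presence_matrix",
    "flags_from_matrix",
    "read_calls_tsv",
    "write_labeled_tsv",
]

TIME_POINTS = ("T0", "T1", "T2", "T3", "T4", "T5", "T6")

DE_NOVO = "de_novo_candidate"
POLYMORPHIC = "polymorphic"


@dataclass(frozen=True)
class InsertionCall:
    """One non-reference L1 detection in one cell line.

    ``detected`` holds the time-point labels at which the junction was seen;
    ``extra_passages`` the earlier-hiPSC-passage labels (e.g. ``p15``) with a
    detection.  Junction sequences accompany flagged detections.
    """

    contig: str
    position: int  # 1-based
    strand: str
    line: str
    detected: frozenset[str]
    extra_passages: frozenset[str] = frozenset()
    jx5: str = ""
    jx3: str = ""
    support: dict[str, int] = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        bad = set(self.detected) - set(TIME_POINTS)
        if bad:
            raise ValueError(f"unknown time points {sorted(bad)}")
        if not self.detected and not self.extra_passages:
            raise ValueError("a call must be detected at >=1 time point or passage")
        if self.detected and not (self.jx5 or self.jx3):
            raise ValueError("flagged detections require a junction sequence")

    @property
    def call_id(self) -> str:
        return f"{self.contig}:{self.position}:{self.line}"


@dataclass(frozen=True)
class KnownInsertionCatalog:
    """Published non-reference germ-line insertions, with match windows."""

    records: tuple[tuple[str, int, int], ...]  # (contig, 1-based pos, window)

    def __post_init__(self):
        for contig, pos, window in self.records:
            if window < 0 or pos < 1:
                raise ValueError("catalog positions are 1-based and windows >= 0")

    def matches(self, contig: str, position: int) -> bool:
        return any(
            c == contig and abs(position - p) <= w for c, p, w in self.records
        )

    @classmethod
    def from_tsv(cls, path, default_window: int = 100) -> "KnownInsertionCatalog":
        df = pd.read_csv(path, sep="\t")
        window = df["window"] if "window" in df else default_window
        df = df.assign(window=window)
        return cls(tuple(zip(df["contig"], df["position"].astype(int), df["window"].astype(int))))

    @classmethod
    def from_bed(cls, path, default_window: int = 100) -> "KnownInsertionCatalog":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["contig", "start", "end"], usecols=[0, 1, 2])
        # BED is 0-based half-open; use the interval start as the 1-based position
        return cls(tuple(
            (c, int(s) + 1, default_window) for c, s, _ in df.itertuples(index=False)
        ))


def _cluster_loci(calls: list[InsertionCall], window: int) -> list[int]:
    """Single-linkage clustering of call positions per contig within window."""
    order = sorted(range(len(calls)), key=lambda i: (calls[i].contig, calls[i].position))
    cluster_of = [0] * len(calls)
    cid = -1
    prev_contig, prev_pos = None, None
    for i in order:
        c = calls[i]
        if c.contig != prev_contig or prev_pos is None or c.position - prev_pos > window:
            cid += 1
        cluster_of[i] = cid
        prev_contig, prev_pos = c.contig, c.position
    return cluster_of


def classify_calls(
    calls: list[InsertionCall],
    catalog: KnownInsertionCatalog,
    lines: set[str] | None = None,
    window: int = 100,
) -> list[str]:
    """Label every call ``de_novo_candidate`` or ``polymorphic``.

    Calls within ``window`` nt on the same contig are grouped as one locus
    across lines before the criteria are applied.  Deterministic and
    invariant to input order.
    """
    if lines is not None:
        unknown = {c.line for c in calls} - set(lines)
        if unknown:
            raise ValueError(f"calls from unassigned lines: {sorted(unknown)}")
    cluster_of = _cluster_loci(calls, window)
    by_cluster: dict[int, list[InsertionCall]] = {}
    for c, cid in zip(calls, cluster_of):
        by_cluster.setdefault(cid, []).append(c)

    labels = []
    for c, cid in zip(calls, cluster_of):
        group = by_cluster[cid]
        lines_detected = {g.line for g in group}
        t0_any = any("T0" in g.detected for g in group)
        known = any(catalog.matches(g.contig, g.position) for g in group)
        de_novo = len(lines_detected) == 1 and not t0_any and not known
        labels.append(DE_NOVO if de_novo else POLYMORPHIC)
    return labels


def presence_matrix(calls: list[InsertionCall]) -> pd.DataFrame:
    """Boolean call x time-point table, rows in input order, columns T0..T6."""
    data = [[tp in c.detected for tp in TIME_POINTS] for c in calls]
    return pd.DataFrame(data, index=[c.call_id for c in calls], columns=list(TIME_POINTS))


def flags_from_matrix(matrix: pd.DataFrame) -> list[frozenset[str]]:
    """Inverse of :func:`presence_matrix` (row order preserved)."""
    return [
        frozenset(tp for tp in TIME_POINTS if bool(row[tp]))
        for _, row in matrix.iterrows()
    ]


# ---------------------------------------------------------------------------
# TSV interface (columns fixed and versioned)

CALLS_TSV_COLUMNS = (
    "contig", "position", "strand", "line", "detected", "extra_passages",
    "jx5", "jx3", "support",
)
CALLS_TSV_VERSION = "calls-tsv-v1"


def read_calls_tsv(path) -> list[InsertionCall]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(CALLS_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calls TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        support = {}
        if row.support:
            for item in row.support.split(","):
                tp, n = item.split(":")
                support[tp] = int(n)
        out.append(
            InsertionCall(
                contig=row.contig,
                position=int(row.position),
                strand=row.strand,
                line=row.line,
                detected=frozenset(filter(None, row.detected.split(","))),
                extra_passages=frozenset(filter(None, row.extra_passages.split(","))),
                jx5=row.jx5,
                jx3=row.jx3,
                support=support,
            )
        )
    return out


def write_labeled_tsv(calls: list[InsertionCall], labels: list[str], path) -> None:
    rows = []
    for c, label in zip(calls, labels):
        rows.append(
            {
                "contig": c.contig,
                "position": c.position,
                "strand": c.strand,
                "line": c.line,
                "detected": ",".join(sorted(c.detected)),
                "extra_passages": ",".join(sorted(c.extra_passages)),
                "jx5": c.jx5,
                "jx3": c.jx3,
                "support": ",".join(f"{k}:{v}" for k, v in sorted(c.support.items())),
                "label": label,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
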