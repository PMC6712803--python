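"""Multi-sample analyses of retrocopy candidates.

Builds the gene-by-sample presence matrix, flags reference relics
(apparent retrocopies called in every sample because the intronless copy
is missing from or paralogous in the reference assembly), counts genes
exclusive to one cell line, subtracts parental from iPSC counts per
donor, tallies candidates by source chromosome, and clusters samples
hierarchically on the presence matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import RECURRENT_RELIC, RetroCandidate

log = logging.getLogger(__name__)

CELL_TYPES = ("parental", "iPSC")


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    cell_type: str
    donor_id: str

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")


@dataclass
class CohortMatrix:
    """Boolean gene x sample presence matrix plus sample metadata."""

    present: pd.DataFrame  # index: gene symbols, columns: sample ids, dtype bool
    samples: list[CohortSample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.present.columns) != ids:
            raise ValueError("matrix columns do not match sample metadata order")
        if len(self.present) and not self.present.any(axis=1).all():
            raise ValueError("presence matrix has an all-false gene row")

    @property
    def genes(self) -> list[str]:
        return list(self.present.index)

    def counts_per_sample(self, exclude: Optional[set[str]] = None) -> dict[str, int]:
        m = self.present
        if exclude:
            m = m.loc[[g for g in m.index if g not in exclude]]
        return {s: int(m[s].sum()) for s in m.columns}


def build_matrix(
    per_sample_candidates: dict[str, list[RetroCandidate]],
    samples: Optional[list[CohortSample]] = None,
) -> CohortMatrix:
    """Rows are the union of candidate gene symbols; an entry is true iff
    the gene was called in that sample."""
    if samples is None:
        samples = [CohortSample(s, "iPSC", s) for s in per_sample_candidates]
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in cohort")
    missing = set(per_sample_candidates) - set(ids)
    if missing:
        raise ValueError(f"candidates given for unknown samples: {sorted(missing)}")
    genes = sorted({c.symbol for cands in per_sample_candidates.values() for c in cands})
    if not genes:
        log.warning("no candidates in any sample; presence matrix is empty")
    data = np.zeros((len(genes), len(ids)), dtype=bool)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for j, sid in enumerate(ids):
        for cand in per_sample_candidates.get(sid, []):
            data[gene_idx[cand.symbol], j] = True
    present = pd.DataFrame(data, index=genes, columns=ids)
    return CohortMatrix(present=present, samples=samples)


def flag_recurrent(
    matrix: CohortMatrix,
    recurrence_fraction: float = 1.0,
    per_sample_candidates: Optional[dict[str, list[RetroCandidate]]] = None,
) -> set[str]:
    """Genes present in >= recurrence_fraction of samples.

    At the default 1.0 this flags genes called in ALL samples — the relic
    pattern of intronless paralogues not assembled in the reference. When
    the originating candidate lists are given, the relic flag is
    propagated onto each matching candidate.
    """
    if len(matrix.present) == 0:
        return set()
    frac = matrix.present.mean(axis=1)
    relics = set(frac.index[frac >= recurrence_fraction])
    if per_sample_candidates is not None:
        for cands in per_sample_candidates.values():
            for cand in cands:
                if cand.symbol in relics:
                    cand.flags.add(RECURRENT_RELIC)
    return relics


def exclusive_counts(
    matrix: CohortMatrix, relics: Optional[set[str]] = None
) -> dict[str, int]:
    """Per sample, the number of genes present in that sample only.

    Relic genes are excluded: a reference artifact seen everywhere is
    never exclusive, and flagged relics are discounted from event counts.
    """
    relics = relics or set()
    out = {s.sample_id: 0 for s in matrix.samples}
    for gene, row in matrix.present.iterrows():
        if gene in relics:
            continue
        holders = row.index[row]
        if len(holders) == 1:
            out[holders[0]] += 1
    return out


def ipsc_minus_parent(
    matrix: CohortMatrix, relics: Optional[set[str]] = None
) -> dict[str, int]:
    """Per iPSC line, its candidate count minus its parental line's count.

    Keys are iPSC sample ids (a donor with several iPSC lines yields one
    entry per line). Negative values are allowed. Donors lacking either
    cell type are skipped with a warning. Relic genes are excluded from
    both counts.
    """
    counts = matrix.counts_per_sample(exclude=relics)
    parents: dict[str, list[str]] = {}
    ipscs: dict[str, list[str]] = {}
    for s in matrix.samples:
        (parents if s.cell_type == "parental" else ipscs).setdefault(
            s.donor_id, []
        ).append(s.sample_id)
    out: dict[str, int] = {}
    for donor, lines in ipscs.items():
        if donor not in parents:
            log.warning("donor %s has iPSC line(s) but no parental sample; skipped", donor)
            continue
        parent_count = sum(counts[p] for p in parents[donor]) / len(parents[donor])
        for line in lines:
            out[line] = int(counts[line] - parent_count)
    for donor in parents:
        if donor not in ipscs:
            log.warning("donor %s has a parental sample but no iPSC line; skipped", donor)
    return out


def chromosome_counts(
    per_sample_candidates: dict[str, list[RetroCandidate]],
    relics: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Sample x chromosome counts of candidates by SOURCE gene position
    (the locus the retrocopy came from, not where it integrated)."""
    relics = relics or set()
    rows = []
    for sid, cands in per_sample_candidates.items():
        for c in cands:
            if c.symbol in relics:
                continue
            rows.append((sid, c.chrom))
    samples = list(per_sample_candidates)
    if not rows:
        return pd.DataFrame(index=pd.Index(samples, name="sample"), dtype=int)
    df = pd.DataFrame(rows, columns=["sample", "chrom"])
    table = pd.crosstab(df["sample"], df["chrom"])
    table = table.reindex(samples, fill_value=0)
    table.index.name = "sample"
    table.columns.name = None
    return table.astype(int)


def cluster_samples(
    matrix: CohortMatrix, metric: str = "jaccard", method: str = "average"
) -> tuple[np.ndarray, list[str], str]:
    """Agglomerative clustering of samples on the boolean presence matrix.

    Returns (linkage matrix, leaf order as sample ids, Newick string).
    Jaccard distance with average linkage by default; identical columns
    merge at height zero. Deterministic for a fixed input.
    """
    if len(matrix.samples) < 2:
        raise ValueError("clustering needs at least 2 samples")
    if len(matrix.present) < 1:
        raise ValueError("clustering needs at least 1 gene row")
    X = matrix.present.to_numpy().T.astype(bool)
    dist = pdist(X, metric=metric)
    dist = np.nan_to_num(dist, nan=0.0)  # all-false pair of columns
    Z = hierarchy.linkage(dist, method=method)
    ids = [s.sample_id for s in matrix.samples]
    leaves = [ids[i] for i in hierarchy.leaves_list(Z)]
    newick = _to_newick(hierarchy.to_tree(Z), ids)
    return Z, leaves, newick


def _to_newick(node, labels: list[str]) -> str:
    def rec(n, parent_height: float) -> str:
        length = max(parent_height - n.dist, 0.0)
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        left = rec(n.left, n.dist)
        right = rec(n.right, n.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(node, node.dist) + ";"


def write_cohort_reports(
    matrix: CohortMatrix,
    per_sample_candidates: dict[str, list[RetroCandidate]],
    out_dir: str | Path,
    recurrence_fraction: float = 1.0,
) -> dict[str, Path]:
    """Write matrix.tsv, exclusive.tsv, subtraction.tsv, chrom_counts.tsv
    and dendrogram.nwk into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    relics = flag_recurrent(matrix, recurrence_fraction, per_sample_candidates)
    paths = {
        "matrix": out_dir / "matrix.tsv",
        "exclusive": out_dir / "exclusive.tsv",
        "subtraction": out_dir / "subtraction.tsv",
        "chrom_counts": out_dir / "chrom_counts.tsv",
        "dendrogram": out_dir / "dendrogram.nwk",
    }
    mat = matrix.present.astype(int).copy()
    mat.insert(0, "relic", [int(g in relics) for g in mat.index])
    mat.index.name = "gene"
    mat.to_csv(paths["matrix"], sep="\t")
    excl = exclusive_counts(matrix, relics)
    with open(paths["exclusive"], "w") as fh:
        fh.write("sample\texclusive_genes\n")
        for sid, n in excl.items():
            fh.write(f"{sid}\t{n}\n")
    sub = ipsc_minus_parent(matrix, relics)
    with open(paths["subtraction"], "w") as fh:
        fh.write("ipsc_sample\tipsc_minus_parent\n")
        for sid, n in sub.items():
            fh.write(f"{sid}\t{n}\n")
    chrom = chromosome_counts(per_sample_candidates, relics)
    chrom.index.name = "sample"
    chrom.to_csv(paths["chrom_counts"], sep="\t")
    if len(matrix.samples) >= 2 and len(matrix.present) >= 1:
        _, _, newick = cluster_samples(matrix)
        paths["dendrogram"].write_text(newick + "\n")
    return paths
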