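"""Per-protein characteristics: conservation, intrinsic disorder, PPI degree.

Conservation is the mean per-residue relative entropy (Kullback-Leibler
divergence) between a protein's alignment-profile rows and a background
amino-acid distribution; intrinsic disorder is summarized as the fraction of
residues labelled disordered by a 3-of-5 majority-vote consensus over five
binary predictor tracks; interconnectedness is the node degree in an
undirected protein-protein interaction network, with a distinguished
"no PPI information" outcome for proteins absent from the network.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError

#: the 20 standard amino acids, alphabetical one-letter codes
AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")

#: default background distribution q: uniform over the 20 amino acids
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

#: majority threshold over the five predictor tracks (fixed, not configurable)
MAJORITY_THRESHOLD = 3
N_PREDICTORS = 5


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

@dataclass
class AlignmentProfile:
    """Position x amino-acid probability matrix for one protein.

    Rows follow the residue order of the sequence; columns follow
    :data:`AA_ORDER`.  Every row is a probability vector.
    """

    accession: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise InputError(f"{self.accession}: profile must be L x 20")
        if np.any(self.matrix < 0):
            raise InputError(f"{self.accession}: negative profile entry")
        sums = self.matrix.sum(axis=1)
        if self.matrix.shape[0] and np.max(np.abs(sums - 1.0)) > 1e-6:
            raise InputError(f"{self.accession}: profile rows must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def _check_background(q: Optional[np.ndarray]) -> np.ndarray:
    if q is None:
        return UNIFORM_BACKGROUND
    q = np.asarray(q, dtype=float)
    if q.shape != (20,):
        raise InputError("background frequencies must have 20 entries")
    if np.any(q <= 0):
        raise InputError("background frequencies must be strictly positive")
    if abs(q.sum() - 1.0) > 1e-6:
        raise InputError("background frequencies must sum to 1")
    return q


def residue_relative_entropy(
    row: Sequence[float], q: Optional[Sequence[float]] = None, unit: str = "nats"
) -> float:
    """Relative entropy sum_a p_a log(p_a / q_a) of one profile row.

    Zero profile entries contribute zero (0 * log 0 := 0).  ``unit`` selects
    natural-log ("nats", default) or base-2 ("bits") units.
    """
    p = np.asarray(row, dtype=float)
    if p.shape != (20,):
        raise InputError("profile row must have 20 entries")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise InputError("profile row must be a probability vector")
    qv = _check_background(None if q is None else np.asarray(q))
    mask = p > 0
    value = float(np.sum(p[mask] * np.log(p[mask] / qv[mask])))
    value = max(value, 0.0)  # clip tiny negative rounding
    if unit == "bits":
        value /= math.log(2.0)
    elif unit != "nats":
        raise InputError(f"unknown unit {unit!r}")
    return value


def protein_conservation(
    profile: AlignmentProfile,
    q: Optional[Sequence[float]] = None,
    unit: str = "nats",
) -> float:
    """Mean per-residue relative entropy over all rows of the profile."""
    if profile.length == 0:
        raise InputError(f"{profile.accession}: empty profile")
    qv = _check_background(None if q is None else np.asarray(q))
    m = profile.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(m > 0, m * np.log(m / qv), 0.0)
    value = float(np.mean(terms.sum(axis=1)))
    value = max(value, 0.0)
    if unit == "bits":
        value /= math.log(2.0)
    elif unit != "nats":
        raise InputError(f"unknown unit {unit!r}")
    return value


# ---------------------------------------------------------------------------
# intrinsic disorder
# ---------------------------------------------------------------------------

def consensus_disorder(tracks: np.ndarray | Sequence[Sequence[int]]) -> np.ndarray:
    """Majority-vote consensus: residue disordered iff >= 3 of 5 tracks say so."""
    t = np.asarray(tracks, dtype=int)
    if t.ndim != 2 or t.shape[0] != N_PREDICTORS:
        raise InputError(f"expected {N_PREDICTORS} predictor tracks")
    if not np.isin(t, (0, 1)).all():
        raise InputError("tracks must be binary")
    return (t.sum(axis=0) >= MAJORITY_THRESHOLD).astype(np.int8)


def disorder_content(consensus: Sequence[int]) -> float:
    """Fraction of residues labelled disordered by the consensus."""
    c = np.asarray(consensus, dtype=int)
    if c.size == 0:
        raise InputError("empty consensus track")
    return float(c.mean())


@dataclass
class DisorderTrackSet:
    """Five binary predictor tracks with their derived consensus."""

    accession: str
    tracks: np.ndarray  # 5 x L, {0,1}
    consensus: np.ndarray = field(init=False)
    content: float = field(init=False)

    def __post_init__(self) -> None:
        self.tracks = np.asarray(self.tracks, dtype=np.int8)
        self.consensus = consensus_disorder(self.tracks)
        self.content = disorder_content(self.consensus)

    @property
    def length(self) -> int:
        return self.tracks.shape[1]


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

class PPINetwork:
    """Undirected simple interaction graph over protein accessions."""

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = nx.Graph() if graph is None else nx.Graph(graph)
        self.graph.remove_edges_from(nx.selfloop_edges(self.graph))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PPINetwork":
        g = nx.Graph()
        g.add_edges_from((a, b) for a, b in edges if a != b)
        return cls(g)

    @classmethod
    def from_edge_list(cls, path: str | Path) -> "PPINetwork":
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                edges.append((a, b))
        return cls.from_edges(edges)

    def __contains__(self, accession: str) -> bool:
        return accession in self.graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, accession: str) -> Optional[int]:
        if accession not in self.graph:
            return None
        return int(self.graph.degree[accession])

    def write_edge_list(self, path: str | Path) -> None:
        lines = sorted(
            "\t".join(sorted((a, b))) for a, b in self.graph.edges()
        )
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def ppi_degree(network: PPINetwork, accession: str) -> Optional[int]:
    """Degree of ``accession``, or None when the protein has no PPI information.

    Absence from the network is not degree zero: such proteins are excluded
    from interconnectedness statistics downstream.
    """
    return network.degree(accession)


# ---------------------------------------------------------------------------
# feature table assembly and I/O
# ---------------------------------------------------------------------------

def compute_feature_table(
    records: Sequence,
    profiles: Optional[dict[str, AlignmentProfile]] = None,
    tracks: Optional[dict[str, DisorderTrackSet]] = None,
    network: Optional[PPINetwork] = None,
    q: Optional[Sequence[float]] = None,
    unit: str = "nats",
    group: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Assemble the per-protein feature table.

    Any of ``profiles``/``tracks``/``network`` may be omitted, leaving the
    corresponding column as NaN.  ``group`` maps accession to an analysis
    group label (e.g. focal / background); defaults to the record's
    regulation label.
    """
    rows = []
    for rec in records:
        acc = rec.accession
        conservation = np.nan
        if profiles is not None and acc in profiles:
            conservation = protein_conservation(profiles[acc], q=q, unit=unit)
        content = np.nan
        if tracks is not None and acc in tracks:
            content = tracks[acc].content
        degree: float = np.nan
        if network is not None:
            d = network.degree(acc)
            if d is not None:
                degree = float(d)
        rows.append(
            {
                "accession": acc,
                "gene_id": rec.gene_id,
                "group": (group or {}).get(acc, rec.regulation),
                "length": rec.length,
                "conservation_nats": conservation,
                "disorder_content": content,
                "degree": degree,
            }
        )
    return pd.DataFrame(rows)


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    out = table.copy()
    out["degree"] = out["degree"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["degree"] = pd.to_numeric(df["degree"], errors="coerce")
    return df


def read_profile(path: str | Path, accession: str) -> AlignmentProfile:
    """Read a profile TSV (header = 20 amino-acid letters, 6-decimal rows).

    Written probabilities are rounded, so raw row sums are accepted within
    1e-4 and rows are renormalized exactly.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != AA_ORDER:
            raise InputError(f"{path}: unexpected profile header")
        matrix = np.array([[float(v) for v in row] for row in reader])
    if matrix.size == 0:
        raise InputError(f"{path}: empty profile")
    sums = matrix.sum(axis=1)
    if np.max(np.abs(sums - 1.0)) > 1e-4:
        raise InputError(f"{path}: profile rows do not sum to 1")
    matrix /= sums[:, None]
    return AlignmentProfile(accession=accession, matrix=matrix)


def write_profile(path: str | Path, profile: AlignmentProfile) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(AA_ORDER)
        for row in profile.matrix:
            w.writerow([f"{v:.6f}" for v in row])


def read_tracks(path: str | Path, accession: str) -> DisorderTrackSet:
    """Read a predictor-track TSV (position + five binary predictor columns)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if len(header) != 1 + N_PREDICTORS or header[0] != "position":
            raise InputError(f"{path}: unexpected track header")
        rows = [[int(v) for v in row[1:]] for row in reader]
    if not rows:
        raise InputError(f"{path}: empty track file")
    return DisorderTrackSet(accession=accession, tracks=np.array(rows).T)


def write_tracks(path: str | Path, trackset: DisorderTrackSet) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["position"] + [f"pred{i + 1}" for i in range(N_PREDICTORS)])
        for i in range(trackset.length):
            w.writerow([i + 1] + [int(v) for v in trackset.tracks[:, i]])
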