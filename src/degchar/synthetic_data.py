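"""Synthetic inputs with planted statistical structure.

Every pipeline input — proteome FASTA, alignment profiles, disorder predictor
tracks, PPI edge list, GO ontology + annotations, and the two
differential-expression gene lists with their gene-to-protein mapping — can
be generated here with controlled effects, so every downstream stage is
testable without external downloads.

Reproducibility model: each generator draws from its own RNG stream derived
from ``(config.seed, stream offset)``; per-protein artifacts (profiles,
tracks) additionally key their substream by ``crc32(accession)`` so that
generating them for a subset of records yields exactly the subset of a full
run.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, GenerationError
from .features import (
    AA_ORDER,
    AlignmentProfile,
    DisorderTrackSet,
    PPINetwork,
    write_profile,
    write_tracks,
)
from .mapping import GeneEntry, ProteinRecord, write_gene_list, write_mapping_table

# fixed stream offsets: modules can be regenerated independently yet reproducibly
_STREAM_PROTEOME = 0
_STREAM_PROFILE = 1
_STREAM_TRACKS = 2
_STREAM_PPI = 3
_STREAM_GO = 4
_STREAM_DEG = 5

_AA_BYTES = np.frombuffer("".join(AA_ORDER).encode(), dtype=np.uint8)

GO_NAMESPACES = ("molecular_function", "biological_process", "cellular_component")
_GO_ASPECT = {"molecular_function": "F", "biological_process": "P",
              "cellular_component": "C"}
_GO_QUALIFIER = {"molecular_function": "enables",
                 "biological_process": "involved_in",
                 "cellular_component": "located_in"}

#: minimum copies of each length value in the central length band, so that
#: exact-length matching downstream always finds a partner
MIN_PER_LENGTH = 20


def go_term_id(k: int) -> str:
    """Identifier of the k-th generated term (1-based); terms 1-3 are roots."""
    return f"GO:{k:07d}"


def go_term_namespace(k: int) -> str:
    if k <= 3:
        return GO_NAMESPACES[k - 1]
    return GO_NAMESPACES[(k - 4) % 3]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, defaulting to the emulated conditions.

    Defaults mirror the study being emulated: 103 focal proteins from two
    55-gene lists overlapping in 6 genes with 5 unmappable ids; a log-normal
    proteome length distribution with median ~412 residues; consensus
    disorder content ~0.09 (focal) vs ~0.18 (background); a heavy-tailed PPI
    network with mean degree ~6; and GO annotations with a strongly enriched
    planted term.
    """

    seed: int = 0
    n_proteome: int = 5000  # background proteins (focal proteins are extra)
    n_focal: int = 103
    length_log_mean: float = math.log(412.0)
    length_log_sd: float = 0.6
    conservation_alpha_focal: float = 1.0
    conservation_alpha_background: float = 0.5
    conservation_uniform: bool = False  # all profile rows uniform (zero RE limit)
    disorder_content_focal: float = 0.09
    disorder_content_background: float = 0.18
    disorder_segment_mean: float = 15.0  # mean disordered run length (residues)
    predictor_flip_rates: tuple[float, ...] = (0.05, 0.05, 0.05, 0.08, 0.08)
    mean_degree: float = 6.0
    degree_exponent: float = 2.5
    ppi_absent_fraction: float = 0.1
    go_n_terms: int = 60
    go_depth: int = 5
    go_base_rate: float = 0.02
    planted_terms: tuple[tuple[str, float, float], ...] = (
        # (term id, focal annotation rate, background annotation rate):
        # a broad, 3x-enriched compartment-like term
        ("GO:0000010", 0.24, 0.08),
    )
    deg_list_sizes: tuple[int, int, int, int] = (55, 55, 6, 5)
    p_up: float = 0.45  # per-gene probability of the "up" direction

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_proteome": self.n_proteome,
            "n_focal": self.n_focal,
            "go_n_terms": self.go_n_terms,
            "go_depth": self.go_depth,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(name, f"must be a positive integer, got {value}")
        fractions = {
            "disorder_content_focal": self.disorder_content_focal,
            "disorder_content_background": self.disorder_content_background,
            "ppi_absent_fraction": self.ppi_absent_fraction,
            "go_base_rate": self.go_base_rate,
            "p_up": self.p_up,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(name, f"must be in [0, 1], got {value}")
        if len(self.predictor_flip_rates) != 5:
            raise ConfigurationError("predictor_flip_rates", "exactly 5 rates required")
        for r in self.predictor_flip_rates:
            if not 0.0 <= r < 0.5:
                raise ConfigurationError(
                    "predictor_flip_rates",
                    f"rates must be in [0, 0.5) — predictors better than chance, got {r}",
                )
        if self.length_log_sd < 0:
            raise ConfigurationError("length_log_sd", "must be >= 0")
        for name in ("conservation_alpha_focal", "conservation_alpha_background"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(name, "Dirichlet concentration must be > 0")
        if self.disorder_segment_mean < 1:
            raise ConfigurationError("disorder_segment_mean", "must be >= 1 residue")
        if self.mean_degree <= 0:
            raise ConfigurationError("mean_degree", "must be > 0")
        if self.degree_exponent <= 2.0:
            raise ConfigurationError(
                "degree_exponent", "must be > 2 for a finite mean degree"
            )
        n_list_a, n_list_b, n_overlap, n_unmappable = self.deg_list_sizes
        for name, v in zip(("n_listA", "n_listB"), (n_list_a, n_list_b)):
            if v <= 0:
                raise ConfigurationError(name, "must be > 0")
        if n_overlap < 0 or n_overlap > min(n_list_a, n_list_b):
            raise ConfigurationError("n_overlap", "must be <= min(list sizes)")
        n_union = n_list_a + n_list_b - n_overlap
        if n_unmappable < 0 or n_unmappable > n_union:
            raise ConfigurationError("n_unmappable", "must be <= union size")
        if self.n_focal < n_union - n_unmappable:
            raise ConfigurationError(
                "n_focal", "focal proteins must cover every mappable gene"
            )
        for term, f_rate, b_rate in self.planted_terms:
            for label, rate in (("focal", f_rate), ("background", b_rate)):
                if not 0.0 <= rate <= 1.0:
                    raise ConfigurationError(
                        "planted_terms", f"{term} {label} rate {rate} not in [0, 1]"
                    )

    @property
    def n_mappable_genes(self) -> int:
        a, b, overlap, unmappable = self.deg_list_sizes
        return a + b - overlap - unmappable


def _record_stream(seed: int, stream: int, accession: str) -> np.random.Generator:
    return np.random.default_rng([seed, stream, zlib.crc32(accession.encode())])


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def _length_support(config: SimulationConfig, n_total: int) -> np.ndarray:
    """Discrete length grid: log-normal quantiles, >= 30 residues.

    Lengths are snapped to ~n/50 grid values so that each value in the
    central band can carry at least MIN_PER_LENGTH proteins (exact-length
    matching downstream relies on this).
    """
    k = max(1, n_total // 50)
    if config.length_log_sd == 0 or k == 1:
        return np.array([max(30, round(math.exp(config.length_log_mean)))])
    probs = (np.arange(k) + 0.5) / k
    values = np.exp(config.length_log_mean + config.length_log_sd * norm.ppf(probs))
    return np.unique(np.maximum(30, np.rint(values).astype(int)))


def _draw_lengths(config: SimulationConfig, rng: np.random.Generator,
                  n_total: int) -> np.ndarray:
    support = _length_support(config, n_total)
    if len(support) == 1:
        return np.full(n_total, support[0])
    raw = np.exp(rng.normal(config.length_log_mean, config.length_log_sd, n_total))
    boundaries = (support[:-1] + support[1:]) / 2.0
    lengths = support[np.searchsorted(boundaries, raw)]

    # repair pass: top up central-band grid values below MIN_PER_LENGTH by
    # reassigning proteins from the most populated values
    lo, hi = np.percentile(lengths, [5, 95])
    band = [v for v in support if lo <= v <= hi]
    counts = {v: int(np.sum(lengths == v)) for v in support}
    floor = {v: MIN_PER_LENGTH if v in band else 0 for v in support}
    for v in band:
        while counts[v] < MIN_PER_LENGTH:
            donors = [w for w in support if counts[w] > floor[w] + 1 and w != v]
            if not donors:
                break
            w = max(donors, key=lambda x: counts[x])
            idx = np.flatnonzero(lengths == w)
            take = int(rng.choice(idx))
            lengths[take] = v
            counts[w] -= 1
            counts[v] += 1
    return lengths


def generate_proteome(config: SimulationConfig) -> list[ProteinRecord]:
    """Background + focal protein records with log-normal lengths.

    The first ``n_focal`` records are the focal set: they carry gene ids from
    the mappable differential-expression genes and an up/down regulation
    label; the rest are background.  Sequences are uniform over the 20
    amino acids (composition does not enter any downstream statistic).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_PROTEOME])
    n_total = config.n_proteome + config.n_focal
    lengths = _draw_lengths(config, rng, n_total)

    n_genes = config.n_mappable_genes
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    directions = {g: ("up" if rng.random() < config.p_up else "down") for g in genes}
    # first n_genes focal proteins get distinct genes; extras are isoforms
    focal_genes = list(genes)
    extra = config.n_focal - n_genes
    if extra > 0:
        focal_genes += [genes[int(i)] for i in rng.integers(0, n_genes, extra)]

    records = []
    for i in range(n_total):
        length = int(lengths[i])
        seq = _AA_BYTES[rng.integers(0, 20, length)].tobytes().decode()
        if i < config.n_focal:
            gene = focal_genes[i]
            regulation = directions[gene]
        else:
            gene = f"BG{i - config.n_focal + 1:05d}"
            regulation = "background"
        records.append(
            ProteinRecord(
                accession=f"SYN{i + 1:06d}",
                gene_id=gene,
                sequence=seq,
                regulation=regulation,
            )
        )
    return records


def write_fasta(path: str | Path, records: Sequence[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} gene={rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# alignment profiles
# ---------------------------------------------------------------------------

def generate_profiles(
    records: Sequence[ProteinRecord],
    config: SimulationConfig,
    out_dir: Optional[str | Path] = None,
) -> dict[str, AlignmentProfile]:
    """Per-residue Dirichlet profile rows; sharper columns for lower alpha.

    Focal records use ``conservation_alpha_focal``, background records
    ``conservation_alpha_background``.  With ``conservation_uniform`` every
    row is exactly uniform (the zero-relative-entropy limit).
    """
    if not records:
        raise GenerationError("no records to profile")
    profiles: dict[str, AlignmentProfile] = {}
    for rec in records:
        rng = _record_stream(config.seed, _STREAM_PROFILE, rec.accession)
        if config.conservation_uniform:
            matrix = np.full((rec.length, 20), 1.0 / 20.0)
        else:
            alpha = (
                config.conservation_alpha_background
                if rec.regulation == "background"
                else config.conservation_alpha_focal
            )
            matrix = rng.dirichlet(np.full(20, alpha), size=rec.length)
        profiles[rec.accession] = AlignmentProfile(rec.accession, matrix)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for acc, prof in profiles.items():
            write_profile(out_dir / f"{acc}.tsv", prof)
    return profiles


# ---------------------------------------------------------------------------
# disorder tracks
# ---------------------------------------------------------------------------

def _true_disorder(rng: np.random.Generator, length: int, content: float,
                   segment_mean: float) -> np.ndarray:
    """Hidden truth from a two-state Markov chain with stationary fraction
    ``content`` and mean disordered run length ``segment_mean``."""
    if content <= 0.0:
        return np.zeros(length, dtype=np.int8)
    if content >= 1.0:
        return np.ones(length, dtype=np.int8)
    p_exit = 1.0 / segment_mean
    p_enter = min(1.0, content / (1.0 - content) / segment_mean)
    state = int(rng.random() < content)
    out = np.empty(length, dtype=np.int8)
    pos = 0
    while pos < length:
        run = int(rng.geometric(p_exit if state else p_enter))
        run = min(run, length - pos)
        out[pos:pos + run] = state
        pos += run
        state = 1 - state
    return out


def generate_disorder_tracks(
    records: Sequence[ProteinRecord],
    config: SimulationConfig,
    out_dir: Optional[str | Path] = None,
) -> dict[str, DisorderTrackSet]:
    """Five noisy binary predictor tracks around a hidden per-residue truth."""
    if not records:
        raise GenerationError("no records to annotate")
    for r in config.predictor_flip_rates:
        if r >= 0.5:
            raise ConfigurationError(
                "predictor_flip_rates", "predictors must be better than chance"
            )
    flip = np.asarray(config.predictor_flip_rates)[:, None]
    tracksets: dict[str, DisorderTrackSet] = {}
    for rec in records:
        rng = _record_stream(config.seed, _STREAM_TRACKS, rec.accession)
        content = (
            config.disorder_content_background
            if rec.regulation == "background"
            else config.disorder_content_focal
        )
        truth = _true_disorder(rng, rec.length, content, config.disorder_segment_mean)
        flips = rng.random((5, rec.length)) < flip
        tracks = np.where(flips, 1 - truth, truth)
        tracksets[rec.accession] = DisorderTrackSet(rec.accession, tracks)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for acc, ts in tracksets.items():
            write_tracks(out_dir / f"{acc}.tsv", ts)
    return tracksets


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def generate_ppi(
    records: Sequence[ProteinRecord],
    config: SimulationConfig,
    out_path: Optional[str | Path] = None,
) -> PPINetwork:
    """Configuration-model network with a discretized power-law degree sequence.

    The degree sequence is drawn from a Pareto law with the configured
    exponent, rescaled so the realized mean degree matches ``mean_degree``
    after simple-graph repair (self-loops and parallel edges removed; random
    edges added/removed to restore the target edge count).  A fraction of
    proteins is left out of the network entirely, emulating proteins without
    PPI information.
    """
    if len(records) < 10:
        raise GenerationError("need at least 10 records for a PPI network")
    rng = np.random.default_rng([config.seed, _STREAM_PPI])
    members = [
        rec.accession
        for rec in records
        if rng.random() >= config.ppi_absent_fraction
    ]
    n = len(members)
    if config.mean_degree >= n - 1:
        raise ConfigurationError("mean_degree", f"must be < n - 1 = {n - 1}")

    a = config.degree_exponent - 1.0  # Pareto shape; mean = a * xm / (a - 1)
    xm = config.mean_degree * (a - 1.0) / a
    draws = xm / (rng.random(n) ** (1.0 / a))
    degrees = np.clip(np.rint(draws).astype(int), 1, n - 1)
    if degrees.sum() % 2:
        degrees[0] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))

    target_edges = round(config.mean_degree * n / 2.0)
    while g.number_of_edges() < target_edges:
        u, v = rng.integers(0, n, 2)
        if u != v and not g.has_edge(int(u), int(v)):
            g.add_edge(int(u), int(v))
    while g.number_of_edges() > target_edges:
        edges = list(g.edges())
        g.remove_edge(*edges[int(rng.integers(len(edges)))])

    g = nx.relabel_nodes(g, dict(enumerate(members)))
    network = PPINetwork(g)
    if out_path is not None:
        network.write_edge_list(out_path)
    return network


# ---------------------------------------------------------------------------
# GO ontology + annotations
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGO:
    """Generated ontology (child -> parent is_a DAG) with direct annotations."""

    graph: nx.DiGraph  # edges child -> parent
    names: dict[str, str]
    namespaces: dict[str, str]
    direct_annotations: dict[str, set[str]]  # accession -> direct term ids

    def roots(self) -> list[str]:
        return [t for t in self.graph if self.graph.out_degree(t) == 0]


def generate_go(
    records: Sequence[ProteinRecord],
    config: SimulationConfig,
    obo_path: Optional[str | Path] = None,
    gaf_path: Optional[str | Path] = None,
) -> SyntheticGO:
    """Rooted per-namespace is_a DAG plus Bernoulli direct annotations.

    Term k lives in namespace ``go_term_namespace(k)``; terms 1-3 are the
    namespace roots.  Planted terms annotate focal proteins at their elevated
    rate; every other non-root term uses ``go_base_rate`` for both groups.
    """
    n_terms = config.go_n_terms
    if n_terms < 3 + len(config.planted_terms):
        raise ConfigurationError("go_n_terms", "too few terms for the plantings")
    planted = {term: (f, b) for term, f, b in config.planted_terms}
    valid_ids = {go_term_id(k) for k in range(4, n_terms + 1)}
    for term in planted:
        if term not in valid_ids:
            raise ConfigurationError(
                "planted_terms", f"{term} is not a generated non-root term"
            )
    rng = np.random.default_rng([config.seed, _STREAM_GO])

    graph = nx.DiGraph()
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    by_level: dict[str, dict[int, list[str]]] = {ns: {0: []} for ns in GO_NAMESPACES}
    level_of: dict[str, int] = {}
    for k in range(1, n_terms + 1):
        term = go_term_id(k)
        ns = go_term_namespace(k)
        graph.add_node(term)
        names[term] = f"synthetic term {k}"
        namespaces[term] = ns
        if k <= 3:
            by_level[ns][0].append(term)
            level_of[term] = 0
            continue
        # candidate parents: same-namespace terms above the depth cap; planted
        # terms stay leaves so their annotation rates are not diluted by
        # descendant annotations propagating through them
        candidates = [
            t for lvl, terms in by_level[ns].items()
            if lvl <= config.go_depth - 1 for t in terms
            if t not in planted
        ]
        if not candidates:
            candidates = [go_term_id(1 + GO_NAMESPACES.index(ns))]
        n_parents = 1 + int(rng.random() < 0.3 and len(candidates) > 1)
        parents = rng.choice(len(candidates), size=n_parents, replace=False)
        parent_terms = [candidates[int(i)] for i in parents]
        for p in parent_terms:
            graph.add_edge(term, p)
        lvl = max(level_of[p] for p in parent_terms) + 1
        level_of[term] = lvl
        by_level[ns].setdefault(lvl, []).append(term)

    if not nx.is_directed_acyclic_graph(graph):
        raise GenerationError("generated ontology contains a cycle")

    direct: dict[str, set[str]] = {rec.accession: set() for rec in records}
    focal = np.array([rec.regulation != "background" for rec in records])
    accessions = [rec.accession for rec in records]
    for k in range(4, n_terms + 1):
        term = go_term_id(k)
        f_rate, b_rate = planted.get(term, (config.go_base_rate, config.go_base_rate))
        rates = np.where(focal, f_rate, b_rate)
        hits = rng.random(len(records)) < rates
        for i in np.flatnonzero(hits):
            direct[accessions[int(i)]].add(term)

    result = SyntheticGO(graph, names, namespaces, direct)
    if obo_path is not None:
        write_obo(obo_path, result)
    if gaf_path is not None:
        write_gaf(gaf_path, result, {r.accession: r.gene_id for r in records})
    return result


def write_obo(path: str | Path, go: SyntheticGO) -> None:
    lines = ["format-version: 1.2", ""]
    for term in sorted(go.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {go.names[term]}")
        lines.append(f"namespace: {go.namespaces[term]}")
        for parent in sorted(go.graph.successors(term)):
            lines.append(f"is_a: {parent} ! {go.names[parent]}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_gaf(path: str | Path, go: SyntheticGO,
              gene_of: dict[str, str]) -> None:
    lines = ["!gaf-version: 2.2"]
    for accession in sorted(go.direct_annotations):
        for term in sorted(go.direct_annotations[accession]):
            ns = go.namespaces[term]
            cols = [""] * 17
            cols[0] = "SYNDB"
            cols[1] = accession
            cols[2] = gene_of.get(accession, accession)
            cols[3] = _GO_QUALIFIER[ns]
            cols[4] = term
            cols[6] = "IEA"
            cols[8] = _GO_ASPECT[ns]
            lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# differential-expression gene lists
# ---------------------------------------------------------------------------

@dataclass
class DEGLists:
    list_a: list[GeneEntry]
    list_b: list[GeneEntry]
    mapping_table: list[tuple[str, str, bool]]  # gene, accession, is_fragment


def generate_deg_lists(
    records: Sequence[ProteinRecord],
    config: SimulationConfig,
    list_a_path: Optional[str | Path] = None,
    list_b_path: Optional[str | Path] = None,
    mapping_path: Optional[str | Path] = None,
) -> DEGLists:
    """Two overlapping gene lists plus the gene-to-protein mapping table.

    The union contains ``n_listA + n_listB - n_overlap`` unique genes, of
    which exactly ``n_unmappable`` never appear in the mapping table.
    Directions are consistent across lists (mappable genes inherit their
    focal proteins' regulation labels).
    """
    n_list_a, n_list_b, n_overlap, n_unmappable = config.deg_list_sizes
    focal = [r for r in records if r.regulation != "background"]
    mappable_genes: list[str] = []
    seen = set()
    for r in focal:
        if r.gene_id not in seen:
            seen.add(r.gene_id)
            mappable_genes.append(r.gene_id)
    n_union = n_list_a + n_list_b - n_overlap
    if len(mappable_genes) != n_union - n_unmappable:
        raise ConfigurationError(
            "deg_list_sizes",
            f"focal records cover {len(mappable_genes)} genes; "
            f"{n_union - n_unmappable} mappable genes required",
        )
    rng = np.random.default_rng([config.seed, _STREAM_DEG])
    direction_of = {r.gene_id: r.regulation for r in focal}
    unmappable = [f"UG{i + 1:05d}" for i in range(n_unmappable)]
    for g in unmappable:
        direction_of[g] = "up" if rng.random() < config.p_up else "down"

    pool = mappable_genes + unmappable
    order = rng.permutation(len(pool))
    pool = [pool[int(i)] for i in order]
    shared = pool[:n_overlap]
    a_only = pool[n_overlap:n_list_a]
    b_only = pool[n_list_a:]
    list_a = [GeneEntry(g, "rnaseq", direction_of[g]) for g in shared + a_only]
    list_b = [GeneEntry(g, "microarray", direction_of[g]) for g in shared + b_only]
    mapping_table = [(r.gene_id, r.accession, False) for r in focal]

    if list_a_path is not None:
        write_gene_list(list_a_path, list_a)
    if list_b_path is not None:
        write_gene_list(list_b_path, list_b)
    if mapping_path is not None:
        write_mapping_table(mapping_path, mapping_table)
    return DEGLists(list_a, list_b, mapping_table)
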