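"""Synthetic-data generator: PARB-like reference panels, primer-bearing
templates and read sets with known truth.

The panel simulator emulates the divergence structure of a tight species
cluster: a random ancestral marker, per-species consensus sequences at a
configured inter-species divergence from the ancestor, and reference/query
sequences at a (much smaller) intra-species divergence from their species
consensus.  Outgroup sequences sit at a larger divergence.  Defaults
(inter 5%, intra 0.5%) echo a tight clade in which assignments remain
unambiguous; mutation is substitution-only by default so that simulated
marker sets stay columnwise homologous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import ReferencePanel
from .insilico_pcr import MismatchModel, PrimerPair, find_binding_sites
from .seqcore import ReadRecord, SequenceRecord, reverse_complement

__all__ = [
    "PanelSimSpec",
    "ReadSimSpec",
    "random_sequence",
    "mutate",
    "simulate_species_panel",
    "plant_primer_sites",
    "simulate_reads",
    "simulate_additive_matrix",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PanelSimSpec:
    """Conditions for a simulated species panel (divergences are expected
    per-site substitution fractions from the respective parent sequence)."""

    n_species: int = 7
    refs_per_species: int = 3
    queries_per_species: int = 20
    marker_length: int = 800
    inter_species_divergence: float = 0.05
    intra_species_divergence: float = 0.005
    outgroup_divergence: float = 0.15
    n_outgroup: int = 2
    indel_rate: float = 0.0  # optional small-indel mode (geometric lengths)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.intra_species_divergence < self.inter_species_divergence
                < self.outgroup_divergence <= 0.75):
            raise ValueError("require 0 <= intra < inter < outgroup <= 0.75")
        if self.marker_length < 200:
            raise ValueError("marker_length must be >= 200")
        if self.n_species < 2 or self.refs_per_species < 1:
            raise ValueError("need >= 2 species and >= 1 reference per species")


@dataclass
class ReadSimSpec:
    read_length: int = 150
    depth: float = 10.0
    error_rate: float = 0.0
    tiling: bool = False  # evenly spaced starts covering both template ends
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.error_rate < 0.2:
            raise ValueError("error_rate must be in [0, 0.2)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator,
           indel_rate: float = 0.0) -> str:
    """Substitute each site with probability ``rate`` (always to a different
    base); optional small indels at ``indel_rate`` per site, lengths
    geometric with p=0.5, insertions and deletions equiprobable."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        # shift by 1..3 positions within ACGT ring: guaranteed different base
        idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(idx + rng.integers(1, 4, size=hits.size)) % 4]
    if indel_rate <= 0:
        return arr.tobytes().decode("ascii")
    out: List[str] = []
    i = 0
    s = arr.tobytes().decode("ascii")
    while i < len(s):
        if rng.random() < indel_rate:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.append(random_sequence(length, rng))
        out.append(s[i])
        i += 1
    return "".join(out) or s[:1]


def simulate_species_panel(spec: PanelSimSpec
                           ) -> Tuple[ReferencePanel, List[SequenceRecord], pd.DataFrame]:
    """Simulate a labeled reference panel, a query set and its truth table.

    Deterministic for a fixed spec (seed included).  Species are named
    ``species_01``..; reference ids carry ``_ref``, the first reference of
    each species is flagged as the type strain; outgroup records derive
    from the ancestor at ``outgroup_divergence``.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = random_sequence(spec.marker_length, rng)
    records: List[SequenceRecord] = []
    labels: Dict[str, str] = {}
    type_flags: Dict[str, bool] = {}
    outgroup_ids = set()
    queries: List[SequenceRecord] = []
    truth_rows = []
    for s in range(spec.n_species):
        species = f"species_{s + 1:02d}"
        consensus = mutate(ancestor, spec.inter_species_divergence, rng,
                           spec.indel_rate)
        for r in range(spec.refs_per_species):
            rid = f"{species}_ref{r + 1}"
            records.append(SequenceRecord(
                rid, mutate(consensus, spec.intra_species_divergence, rng,
                            spec.indel_rate),
                f"simulated reference of {species}"))
            labels[rid] = species
            type_flags[rid] = r == 0
        for q in range(spec.queries_per_species):
            qid = f"{species}_query{q + 1}"
            queries.append(SequenceRecord(
                qid, mutate(consensus, spec.intra_species_divergence, rng,
                            spec.indel_rate),
                f"simulated query of {species}"))
            truth_rows.append({"query_id": qid, "true_species": species})
    for o in range(spec.n_outgroup):
        oid = f"outgroup_{o + 1}"
        records.append(SequenceRecord(
            oid, mutate(ancestor, spec.outgroup_divergence, rng, spec.indel_rate),
            "simulated outgroup"))
        labels[oid] = f"outgroup_taxon_{o + 1}"
        type_flags[oid] = False
        outgroup_ids.add(oid)
    panel = ReferencePanel(records, labels, type_flags, outgroup_ids)
    truth = pd.DataFrame(truth_rows, columns=["query_id", "true_species"])
    return panel, queries, truth


def plant_primer_sites(
    template: SequenceRecord,
    pair: PrimerPair,
    product_length: int,
    position: int,
    rng: Optional[np.random.Generator] = None,
    model: Optional[MismatchModel] = None,
    max_tries: int = 50,
) -> SequenceRecord:
    """Write the pair's primer sites into a template so the outermost span
    is exactly ``product_length``, re-randomizing background sequence that
    happens to create extra binding sites.

    The forward primer goes in at ``position`` on the plus strand; the
    reverse primer's reverse complement ends at ``position + product_length``.
    """
    flen, rlen = len(pair.forward), len(pair.reverse)
    if product_length < flen + rlen:
        raise ValueError("product_length smaller than the two primer lengths")
    if position < 0 or position + product_length > len(template):
        raise ValueError("planted product does not fit in the template")
    rng = rng or np.random.default_rng(0)
    model = model or MismatchModel()
    fwd_seq = pair.forward.sequence
    rev_rc = reverse_complement(pair.reverse.sequence)
    f_start, f_end = position, position + flen
    r_end = position + product_length
    r_start = r_end - rlen

    base = list(template.residues)
    base[f_start:f_end] = fwd_seq
    base[r_start:r_end] = rev_rc
    planted_spans = [(f_start, f_end), (r_start, r_end)]

    for _ in range(max_tries):
        candidate = SequenceRecord(template.id, "".join(base), template.description)
        extras = []
        found_fwd = found_rev = False
        for primer, is_fwd in ((pair.forward, True), (pair.reverse, False)):
            for site in find_binding_sites(primer, candidate, model):
                if is_fwd and (site.start, site.end, site.strand) == (f_start, f_end, "+"):
                    found_fwd = True
                elif not is_fwd and (site.start, site.end, site.strand) == (r_start, r_end, "-"):
                    found_rev = True
                elif (site.start, site.end) not in planted_spans:
                    extras.append(site)
        if not extras and found_fwd and found_rev:
            return candidate
        # re-randomize the background covered by each unintended site
        for site in extras:
            for i in range(site.start, site.end):
                if any(lo <= i < hi for lo, hi in planted_spans):
                    continue
                base[i] = random_sequence(1, rng)
    raise RuntimeError(
        f"could not plant {pair.pair_name!r} without collateral sites "
        f"after {max_tries} tries"
    )


def simulate_additive_matrix(
    n_taxa: int, rng: np.random.Generator,
    pendant_range: Tuple[float, float] = (0.05, 0.5),
) -> Tuple[List[str], np.ndarray, set]:
    """Random unrooted binary tree -> exact additive distance matrix.

    Returns taxon labels ``t0..``, the matrix, and the generating tree's
    non-trivial bipartitions as normalized frozensets of labels (the side
    not containing ``t0``) — the ground truth for tree-reconstruction
    oracles.
    """
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa for a non-trivial topology")
    adj: Dict[int, Dict[int, float]] = {}

    def add_edge(u: int, v: int, w: float) -> None:
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    nxt = n_taxa
    for leaf in range(3):
        add_edge(leaf, nxt, float(rng.uniform(*pendant_range)))
    edges = [(0, nxt), (1, nxt), (2, nxt)]
    nxt += 1
    for leaf in range(3, n_taxa):
        u, v = edges[int(rng.integers(len(edges)))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid = nxt
        nxt += 1
        split = w * float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, split)
        add_edge(v, mid, w - split)
        add_edge(leaf, mid, float(rng.uniform(*pendant_range)))
        edges.remove((u, v))
        edges += [(u, mid), (v, mid), (leaf, mid)]

    from collections import deque

    D = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        queue = deque([s])
        while queue:
            x = queue.popleft()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    queue.append(y)
        for t in range(n_taxa):
            D[s, t] = dist[t]

    taxa = [f"t{i}" for i in range(n_taxa)]
    all_labels = frozenset(taxa)
    bips = set()
    for u in adj:
        for v in adj[u]:
            if not (u < v and u >= n_taxa and v >= n_taxa):
                continue  # internal edges only
            comp = {u}
            stack = [u]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if (x, y) == (u, v) or y in comp:
                        continue
                    comp.add(y)
                    stack.append(y)
            side = frozenset(f"t{i}" for i in range(n_taxa) if i in comp)
            norm = side if "t0" not in side else all_labels - side
            if 1 < len(norm) < n_taxa - 1:
                bips.add(norm)
    return taxa, D, bips


def simulate_reads(template: SequenceRecord, spec: ReadSimSpec) -> List[ReadRecord]:
    """Uniform-start substitution-error reads to a target mean depth; half
    of the reads (in expectation) are reverse-complemented."""
    L = len(template)
    if spec.read_length > L:
        raise ValueError("read_length exceeds template length")
    rng = np.random.default_rng(spec.seed)
    n_reads = int(np.ceil(spec.depth * L / spec.read_length))
    if spec.tiling:
        starts = np.linspace(0, L - spec.read_length, n_reads).round().astype(int)
    else:
        starts = rng.integers(0, L - spec.read_length + 1, size=n_reads)
    reads: List[ReadRecord] = []
    for i, start in enumerate(starts):
        seq = template.residues[start : start + spec.read_length]
        seq = mutate(seq, spec.error_rate, rng)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(ReadRecord(f"read_{i + 1:05d}", seq))
    return reads
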