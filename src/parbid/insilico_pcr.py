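"""In-silico diagnostic PCR: primer-site scanning, amplicon prediction and
the species-discriminating panel decision table.

The hybridization model is a mismatch-count surrogate for annealing at a
fixed temperature: a primer binds where the total number of IUPAC-aware
mismatches is at most ``max_mismatch`` and the 3'-terminal ``clamp_len``
bases carry at most ``clamp_mismatch`` mismatches.  A template is called to
a species when exactly one panel reaction is positive (an amplicon of the
expected size exists); zero positives is "indeterminate", more than one is
"ambiguous".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import yaml

from .seqcore import IUPAC_SETS, SequenceRecord, reverse_complement

__all__ = [
    "Primer",
    "PrimerPair",
    "PanelDefinition",
    "BindingSite",
    "Amplicon",
    "PanelResult",
    "MismatchModel",
    "find_binding_sites",
    "predict_amplicons",
    "run_panel",
    "extract_marker",
    "load_panel",
    "default_panel",
    "NoAmplificationError",
    "MultipleProductsError",
]

INDETERMINATE = "indeterminate"
AMBIGUOUS = "ambiguous"

# 4-bit encoding: one bit per elementary base, so two codes are compatible
# iff their masks intersect.  'N' == 0b1111 matches everything.
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()}
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _code, _mask in _CODE_MASK.items():
    _MASK_LUT[ord(_code)] = _mask
_N_MASK = _CODE_MASK["N"]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _MASK_LUT[arr]
    if (masks == 0).any():
        bad = chr(arr[int(np.argmax(masks == 0))])
        raise ValueError(f"non-IUPAC character {bad!r} in sequence")
    return masks


class NoAmplificationError(RuntimeError):
    """Virtual amplification produced no product."""


class MultipleProductsError(RuntimeError):
    """Virtual amplification produced more than one product."""


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # 5'->3' IUPAC

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 10:
            raise ValueError(f"primer {self.name!r}: length must be >= 10")
        if "-" in seq:
            raise ValueError(f"primer {self.name!r}: gaps not allowed")
        _encode(seq)  # alphabet check

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    pair_name: str
    forward: Primer
    reverse: Primer
    cognate_species: str = ""
    expected_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.forward.sequence == self.reverse.sequence:
            raise ValueError(f"pair {self.pair_name!r}: forward == reverse primer")
        if self.expected_size is not None and self.expected_size <= 0:
            raise ValueError(f"pair {self.pair_name!r}: expected_size must be > 0")


@dataclass
class MismatchModel:
    """Hybridization stringency knobs shared by all scans."""

    max_mismatch: int = 2
    clamp_len: int = 3
    clamp_mismatch: int = 0
    count_n_as_half: bool = False


@dataclass
class PanelDefinition:
    pairs: List[PrimerPair]
    size_tolerance: float = 0.15
    max_product: int = 3000
    mismatch_model: MismatchModel = field(default_factory=MismatchModel)

    def __post_init__(self) -> None:
        species = [p.cognate_species for p in self.pairs]
        if len(set(species)) != len(species):
            raise ValueError("cognate_species must be unique across panel pairs")


@dataclass(frozen=True)
class BindingSite:
    """Primer footprint on the plus strand of the template.

    ``mismatch_positions`` are 0-based positions along the primer (5'->3'),
    so the 3' clamp is the last ``clamp_len`` positions for either strand.
    """

    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: float
    mismatch_positions: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int
    length: int
    forward_site: BindingSite
    reverse_site: BindingSite
    sequence: str

    def __post_init__(self) -> None:
        if self.length != self.end - self.start:
            raise ValueError("amplicon length inconsistent with coordinates")


@dataclass
class PanelResult:
    template_id: str
    per_pair: Dict[str, Tuple[bool, List[Amplicon]]]
    call: str

    @property
    def positives(self) -> List[str]:
        return [name for name, (pos, _) in self.per_pair.items() if pos]


def _scan_strand(
    primer_masks: np.ndarray,
    template_masks: np.ndarray,
    model: MismatchModel,
    *,
    on_minus: bool,
) -> List[Tuple[int, float, Tuple[int, ...]]]:
    """Scan one strand; returns (start, mismatches, primer-coord positions)."""
    m = len(primer_masks)
    n = len(template_masks)
    if n < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template_masks, m)
    mism = (windows & primer_masks) == 0  # (n-m+1, m)
    counts = mism.sum(axis=1).astype(float)
    if model.count_n_as_half:
        # template N matched the primer trivially; optionally charge 1/2 each
        n_matched = (~mism) & (windows == _N_MASK)
        counts = counts + 0.5 * n_matched.sum(axis=1)
    # primer coordinate of window offset i: i on '+', m-1-i on '-'
    if on_minus:
        clamp_cols = slice(0, model.clamp_len)
    else:
        clamp_cols = slice(m - model.clamp_len, m)
    clamp_counts = mism[:, clamp_cols].sum(axis=1)
    ok = np.flatnonzero((counts <= model.max_mismatch) & (clamp_counts <= model.clamp_mismatch))
    out = []
    for i in ok:
        cols = np.flatnonzero(mism[i])
        if on_minus:
            positions = tuple(sorted(int(m - 1 - c) for c in cols))
        else:
            positions = tuple(int(c) for c in cols)
        out.append((int(i), float(counts[i]), positions))
    return out


def find_binding_sites(
    primer: Primer,
    template: SequenceRecord,
    model: Optional[MismatchModel] = None,
) -> List[BindingSite]:
    """Find all qualifying binding sites of ``primer`` on both strands.

    Sites are reported in plus-strand coordinates, sorted by start; a '-'
    site means the primer anneals to the plus strand shown (its 3' end at
    ``site.start``).
    """
    model = model or MismatchModel()
    tmpl = _encode(template.residues)
    sites: List[BindingSite] = []
    fwd = _encode(primer.sequence)
    for start, mm, pos in _scan_strand(fwd, tmpl, model, on_minus=False):
        sites.append(BindingSite(start, start + len(primer), "+", mm, pos))
    rev = _encode(reverse_complement(primer.sequence))
    for start, mm, pos in _scan_strand(rev, tmpl, model, on_minus=True):
        sites.append(BindingSite(start, start + len(primer), "-", mm, pos))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    pair: PrimerPair,
    template: SequenceRecord,
    max_product: int = 3000,
    model: Optional[MismatchModel] = None,
) -> List[Amplicon]:
    """Enumerate all products with inward-facing 3' ends up to ``max_product``.

    Both arrangements are considered: forward primer on '+' with reverse on
    '-', and the mirrored arrangement (reverse on '+', forward on '-').
    """
    model = model or MismatchModel()
    if len(template) < min(len(pair.forward), len(pair.reverse)):
        return []
    f_sites = find_binding_sites(pair.forward, template, model)
    r_sites = find_binding_sites(pair.reverse, template, model)
    amplicons: List[Amplicon] = []

    def combine(plus_sites: List[BindingSite], minus_sites: List[BindingSite],
                plus_is_forward: bool) -> None:
        for p in plus_sites:
            if p.strand != "+":
                continue
            for q in minus_sites:
                if q.strand != "-":
                    continue
                if q.start < p.end:  # 3' ends must face inward, no overlap
                    continue
                length = q.end - p.start
                if length > max_product:
                    continue
                fwd_site, rev_site = (p, q) if plus_is_forward else (q, p)
                amplicons.append(
                    Amplicon(
                        start=p.start,
                        end=q.end,
                        length=length,
                        forward_site=fwd_site,
                        reverse_site=rev_site,
                        sequence=template.residues[p.start : q.end],
                    )
                )

    combine(f_sites, r_sites, plus_is_forward=True)
    combine(r_sites, f_sites, plus_is_forward=False)
    amplicons.sort(key=lambda a: (a.start, a.end))
    return amplicons


def _size_concordant(amplicons: List[Amplicon], expected: Optional[int], tol: float) -> bool:
    if expected is None:
        return bool(amplicons)
    lo, hi = expected * (1 - tol), expected * (1 + tol)
    return any(lo <= a.length <= hi for a in amplicons)


def run_panel(panel: PanelDefinition, template: SequenceRecord) -> PanelResult:
    """Run the full diagnostic panel and apply the exactly-one decision rule."""
    per_pair: Dict[str, Tuple[bool, List[Amplicon]]] = {}
    for pair in panel.pairs:
        amps = predict_amplicons(pair, template, panel.max_product, panel.mismatch_model)
        positive = bool(amps) and _size_concordant(amps, pair.expected_size, panel.size_tolerance)
        per_pair[pair.pair_name] = (positive, amps)
    positives = [p for p in panel.pairs if per_pair[p.pair_name][0]]
    if len(positives) == 1:
        call = positives[0].cognate_species
    elif not positives:
        call = INDETERMINATE
    else:
        call = AMBIGUOUS
    return PanelResult(template.id, per_pair, call)


def extract_marker(
    template: SequenceRecord,
    anchor_pair: PrimerPair,
    trim_primers: bool = False,
    max_product: int = 3000,
    model: Optional[MismatchModel] = None,
) -> SequenceRecord:
    """Virtually amplify a marker region with anchor primers.

    Exactly one product is required; the anchor primer sequences must be
    supplied by the caller (they are assay configuration, not packaged data).
    """
    amps = predict_amplicons(anchor_pair, template, max_product, model)
    if not amps:
        raise NoAmplificationError(
            f"no amplification of {template.id!r} with pair {anchor_pair.pair_name!r}"
        )
    if len(amps) > 1:
        raise MultipleProductsError(
            f"{len(amps)} products from {template.id!r} with pair {anchor_pair.pair_name!r}"
        )
    amp = amps[0]
    seq = amp.sequence
    if trim_primers:
        # outermost bases belong to whichever primer sits on each end
        left = amp.forward_site if amp.forward_site.strand == "+" else amp.reverse_site
        right = amp.reverse_site if amp.forward_site.strand == "+" else amp.forward_site
        seq = seq[(left.end - amp.start) : (right.start - amp.start)]
    marker_id = f"{template.id}|{anchor_pair.pair_name}"
    return SequenceRecord(marker_id, seq, f"virtual amplicon {amp.start}-{amp.end}")


def load_panel(source: Union[str, Path, dict]) -> PanelDefinition:
    """Load a panel definition from a YAML file (or a parsed mapping)."""
    if isinstance(source, dict):
        data = source
    else:
        data = yaml.safe_load(Path(source).read_text())
    pairs = []
    for entry in data["pairs"]:
        pairs.append(
            PrimerPair(
                pair_name=entry["pair_name"],
                forward=Primer(entry["forward"]["name"], entry["forward"]["sequence"]),
                reverse=Primer(entry["reverse"]["name"], entry["reverse"]["sequence"]),
                cognate_species=entry.get("cognate_species", ""),
                expected_size=entry.get("expected_size"),
            )
        )
    model_data = data.get("mismatch_model", {})
    return PanelDefinition(
        pairs=pairs,
        size_tolerance=float(data.get("size_tolerance", 0.15)),
        max_product=int(data.get("max_product", 3000)),
        mismatch_model=MismatchModel(**model_data) if model_data else MismatchModel(),
    )


def default_panel() -> PanelDefinition:
    """The packaged 4-pair PARB-clade diagnostic panel (mani/mhyb/mppi/mpin)."""
    text = resources.files("parbid.data").joinpath("default_panel.yml").read_text()
    return load_panel(yaml.safe_load(text))
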