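"""Per-protein feature extraction: the 188-feature table.

Feature blocks, in fixed order:

====================  =====  ==============================================
block                 width  content
====================  =====  ==============================================
disorder                  4  fraction disordered; number of disordered
                             segments; segments >= 30 aa; segments >= 50 aa
ppin_summary              6  node degree; neighbor averages of pI,
                             molecular weight and sequence length; pooled
                             neighbor disorder; isolated-node flag
node2vec                128  random-walk network embedding dimensions
physchem                 10  molecular weight, aromaticity, instability
                             index, isoelectric point, GRAVY, flexibility,
                             length, helix/turn/sheet fractions
physchem_per_degree      10  each physchem feature / (degree + 1)
pos2_aa                  20  indicator of the residue at position 2 (the
                             N-end-rule position after the initiator Met)
pos2_group                5  the same indicator grouped into aliphatic /
                             aromatic / charged / tiny / diverse classes
degron                    5  anchored terminal degradation signals NM1-3
                             (N-terminal) and CM1/CM2 (C-terminal)
====================  =====  ==============================================

Physicochemical values come from Biopython's ProteinAnalysis (Lobry
aromaticity, Guruprasad instability, Kyte-Doolittle hydropathy, Vihinen
flexibility). Degron grammars are compiled from configurable residue
classes: the hydrophobic (phi), basic and polar sets default to the
ClpXP-motif literature but are overridable because different choices
change which sequences match.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from . import embedding as _embedding

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Sentinel written where a feature is undefined (missing disorder input,
#: sequences shorter than the flexibility window, isolated-node neighbor
#: averages use 0 instead — see per-feature docstrings).
MISSING = np.nan

PHYSCHEM_NAMES = (
    "mol_weight",
    "aromaticity",
    "instability",
    "isoelectric_point",
    "gravy",
    "flexibility",
    "length",
    "helix_frac",
    "turn_frac",
    "sheet_frac",
)

POS2_GROUPS = ("aliphatic", "aromatic", "charged", "tiny", "diverse")
DEGRON_NAMES = ("NM1", "NM2", "NM3", "CM1", "CM2")


@dataclass
class AminoAcidClasses:
    """Residue classes used by the position-2 grouping and degron grammars."""

    aliphatic: frozenset = frozenset("IVL")
    aromatic: frozenset = frozenset("FYWH")
    charged: frozenset = frozenset("KRDE")
    tiny: frozenset = frozenset("GACS")
    diverse: frozenset = frozenset("TMQNP")
    hydrophobic: frozenset = frozenset("AVLIMFWY")  # phi in the motif grammars
    basic: frozenset = frozenset("KRH")
    polar: frozenset = frozenset("STNQCYHG")

    def __post_init__(self) -> None:
        groups = [self.aliphatic, self.aromatic, self.charged, self.tiny,
                  self.diverse]
        union = set().union(*groups)
        if union != STANDARD_AA or sum(len(g) for g in groups) != 20:
            raise ValueError("position-2 groups must partition the 20 residues")

    def group_of(self, residue: str) -> str:
        for name in POS2_GROUPS:
            if residue in getattr(self, name):
                return name
        raise ValueError(f"non-standard residue {residue!r}")


DEFAULT_CLASSES = AminoAcidClasses()


@dataclass
class ProteinRecord:
    """One protein's sequence and optional per-residue disorder calls."""

    protein_id: str
    sequence: str
    disorder: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(
                f"{self.protein_id}: non-standard residues {sorted(bad)}"
            )
        if self.disorder is not None:
            if len(self.disorder) != len(self.sequence):
                raise ValueError("disorder string length must match sequence")
            if set(self.disorder) - {"0", "1"}:
                raise ValueError("disorder string must be binary")


def disorder_features(disorder: str | None) -> dict[str, float]:
    """Intrinsic-disorder summary: fraction and segment counts.

    A segment is a maximal run of disordered ('1') residues; segments of
    at least 30 and at least 50 residues are counted separately. Missing
    input yields the missing-value sentinel for all four features.
    """
    names = ("disorder_frac", "disorder_nseg", "disorder_nseg30",
             "disorder_nseg50")
    if disorder is None:
        warnings.warn("missing disorder input; sentinel features emitted")
        return {n: MISSING for n in names}
    runs = [len(r) for r in re.findall(r"1+", disorder)]
    return {
        "disorder_frac": disorder.count("1") / len(disorder),
        "disorder_nseg": float(len(runs)),
        "disorder_nseg30": float(sum(r >= 30 for r in runs)),
        "disorder_nseg50": float(sum(r >= 50 for r in runs)),
    }


def physchem_features(sequence: str) -> dict[str, float]:
    """Ten physicochemical descriptors of a sequence.

    Sequences shorter than the 9-residue flexibility window get the
    sentinel 0 for flexibility with a warning; everything else is
    defined for any sequence of length >= 2.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    pa = ProteinAnalysis(sequence)
    if len(sequence) >= 9:
        flex = float(np.mean(pa.flexibility()))
    else:
        warnings.warn("sequence shorter than flexibility window; sentinel 0")
        flex = 0.0
    helix, turn, sheet = pa.secondary_structure_fraction()
    return {
        "mol_weight": pa.molecular_weight(),
        "aromaticity": pa.aromaticity(),
        "instability": pa.instability_index(),
        "isoelectric_point": pa.isoelectric_point(),
        "gravy": pa.gravy(),
        "flexibility": flex,
        "length": float(len(sequence)),
        "helix_frac": helix,
        "turn_frac": turn,
        "sheet_frac": sheet,
    }


def pos2_features(
    sequence: str, classes: AminoAcidClasses = DEFAULT_CLASSES
) -> dict[str, float]:
    """Indicators for the residue at position 2 (after the initiator Met).

    Exactly one of the 20 per-residue indicators and exactly one of the
    five group indicators is 1 for any sequence of length >= 2; a
    length-1 sequence yields all zeros with a warning.
    """
    out = {f"pos2_{aa}": 0.0 for aa in sorted(STANDARD_AA)}
    out.update({f"pos2grp_{g}": 0.0 for g in POS2_GROUPS})
    if len(sequence) < 2:
        warnings.warn("sequence too short for a position-2 residue")
        return out
    aa2 = sequence[1]
    out[f"pos2_{aa2}"] = 1.0
    out[f"pos2grp_{classes.group_of(aa2)}"] = 1.0
    return out


def _charclass(residues: frozenset) -> str:
    return "[" + "".join(sorted(residues)) + "]"


def compile_degron_patterns(
    classes: AminoAcidClasses = DEFAULT_CLASSES,
) -> dict[str, re.Pattern]:
    """Compile the five degradation-signal grammars to anchored regexes.

    N-terminal signals: NM1 = polar, T-or-phi, phi, basic, phi;
    NM2 = Met, basic, phi, phi, phi, any 5, phi;
    NM3 = phi, any, polar, any, polar, any, basic, polar.
    C-terminal signals: CM1 = ...LAA, CM2 = ...RRKKAI.
    """
    phi = _charclass(classes.hydrophobic)
    basic = _charclass(classes.basic)
    polar = _charclass(classes.polar)
    t_or_phi = _charclass(classes.hydrophobic | {"T"})
    return {
        "NM1": re.compile(f"{polar}{t_or_phi}{phi}{basic}{phi}"),
        "NM2": re.compile(f"M{basic}{phi}{phi}{phi}.{{5}}{phi}"),
        "NM3": re.compile(f"{phi}.{polar}.{polar}.{basic}{polar}"),
        "CM1": re.compile("LAA$"),
        "CM2": re.compile("RRKKAI$"),
    }


def degron_features(
    sequence: str,
    classes: AminoAcidClasses = DEFAULT_CLASSES,
    nterm_offset: str = "either",
) -> dict[str, float]:
    """Anchored presence (0/1) of the five terminal degradation signals.

    N-terminal motifs NM1 and NM3 are matched at the very N terminus;
    ``nterm_offset`` selects whether the match may start at residue 1
    (including the initiator Met, ``"met"``), at residue 2 (after the
    Met, ``"no_met"``), or at either position (``"either"``, default).
    NM2 explicitly requires the initiator Met. C-terminal motifs CM1 and
    CM2 must end the sequence.
    """
    if nterm_offset not in ("either", "met", "no_met"):
        raise ValueError("nterm_offset must be 'either', 'met' or 'no_met'")
    pats = compile_degron_patterns(classes)
    offsets = {"either": (0, 1), "met": (0,), "no_met": (1,)}[nterm_offset]
    out = {}
    for name in ("NM1", "NM3"):
        out[name] = float(
            any(pats[name].match(sequence, off) for off in offsets)
        )
    out["NM2"] = float(bool(pats["NM2"].match(sequence)))
    out["CM1"] = float(bool(pats["CM1"].search(sequence)))
    out["CM2"] = float(bool(pats["CM2"].search(sequence)))
    return {k: out[k] for k in DEGRON_NAMES}


def network_summary_features(
    protein_id,
    graph: nx.Graph,
    attributes: pd.DataFrame,
    disorder_counts: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Interaction-network context of one protein.

    ``attributes`` is indexed by protein id with columns
    ``isoelectric_point``, ``mol_weight`` and ``length``.
    ``disorder_counts`` (same index) has a column ``n_disordered``; the
    neighbor disorder feature pools it as total disordered residues
    across neighbors divided by total neighbor length. A protein absent
    from the graph is treated as isolated; neighbor averages of isolated
    proteins use the sentinel 0, matching the zero convention of the
    embedding block.
    """
    if protein_id in graph:
        neighbors = list(graph.neighbors(protein_id))
    else:
        warnings.warn(f"{protein_id} absent from network; treated as isolated")
        neighbors = []
    degree = float(len(neighbors))
    if not neighbors:
        return {
            "degree": 0.0,
            "nbr_pi_mean": 0.0,
            "nbr_mw_mean": 0.0,
            "nbr_len_mean": 0.0,
            "nbr_disorder": 0.0,
            "isolated": 1.0,
        }
    sub = attributes.loc[neighbors]
    if disorder_counts is not None:
        dsub = disorder_counts.loc[neighbors]
        nbr_dis = float(dsub["n_disordered"].sum() / sub["length"].sum())
    else:
        nbr_dis = MISSING
    return {
        "degree": degree,
        "nbr_pi_mean": float(sub["isoelectric_point"].mean()),
        "nbr_mw_mean": float(sub["mol_weight"].mean()),
        "nbr_len_mean": float(sub["length"].mean()),
        "nbr_disorder": nbr_dis,
        "isolated": 0.0,
    }


def per_degree_features(physchem: dict[str, float], degree: float) -> dict:
    """Connectivity-normalized physicochemistry: each value / (degree+1).

    The +1 pseudo-neighbor keeps the transform defined for isolated
    nodes.
    """
    if degree < 0:
        raise ValueError("degree must be non-negative")
    return {
        f"{name}_per_degree": physchem[name] / (degree + 1.0)
        for name in PHYSCHEM_NAMES
    }


def feature_names(dims: int = 128) -> list[str]:
    """The canonical 188 feature names in block order."""
    names = ["disorder_frac", "disorder_nseg", "disorder_nseg30",
             "disorder_nseg50"]
    names += ["degree", "nbr_pi_mean", "nbr_mw_mean", "nbr_len_mean",
              "nbr_disorder", "isolated"]
    names += [f"n2v_{i:03d}" for i in range(dims)]
    names += list(PHYSCHEM_NAMES)
    names += [f"{n}_per_degree" for n in PHYSCHEM_NAMES]
    names += [f"pos2_{aa}" for aa in sorted(STANDARD_AA)]
    names += [f"pos2grp_{g}" for g in POS2_GROUPS]
    names += list(DEGRON_NAMES)
    return names


def assemble_feature_table(
    records: list[ProteinRecord],
    graph: nx.Graph,
    classes: AminoAcidClasses = DEFAULT_CLASSES,
    embed_dims: int = 128,
    embed_seed: int = 0,
    embed_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Build the full 188-column feature table, indexed by protein id.

    All inputs are keyed by protein id; duplicate ids raise. The network
    embedding is computed once for the whole graph with a fixed seed.
    """
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")

    phys = {r.protein_id: physchem_features(r.sequence) for r in records}
    attributes = pd.DataFrame(phys).T[["isoelectric_point", "mol_weight",
                                       "length"]]
    disorder_counts = pd.DataFrame(
        {
            "n_disordered": {
                r.protein_id: (r.disorder.count("1") if r.disorder else 0)
                for r in records
            }
        }
    )
    emb = _embedding.embed_network(
        graph, dims=embed_dims, seed=embed_seed, **(embed_kwargs or {})
    )
    zero_vec = np.zeros(embed_dims)

    rows = {}
    for r in records:
        row: dict[str, float] = {}
        row.update(disorder_features(r.disorder) if r.disorder is not None
                   else disorder_features(None))
        net = network_summary_features(r.protein_id, graph, attributes,
                                       disorder_counts)
        row.update(net)
        vec = emb.get(r.protein_id, zero_vec)
        row.update({f"n2v_{i:03d}": float(v) for i, v in enumerate(vec)})
        row.update(phys[r.protein_id])
        row.update(per_degree_features(phys[r.protein_id], net["degree"]))
        row.update(pos2_features(r.sequence, classes))
        row.update(degron_features(r.sequence, classes))
        rows[r.protein_id] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table[feature_names(embed_dims)]
    table.index.name = "protein_id"
    if embed_dims == 128 and table.shape[1] != 188:
        raise AssertionError("feature table must have exactly 188 columns")
    return table
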