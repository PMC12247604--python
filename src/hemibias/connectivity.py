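"""Within- and between-subject Fisher-z connectivity tables.

Every unordered pair of the ``2 * n_regions`` bilateral nodes of a network
is classified as

* ``inter_corresponding`` — the same region in opposite hemispheres
  (homotopic, e.g. lOFA:rOFA),
* ``inter_noncorresponding`` — different regions in opposite hemispheres
  (e.g. lOFA:rFFA),
* ``intra`` — different regions in the same hemisphere (e.g. rOFA:rFFA).

Within-subject tables correlate one subject's node series with each other;
between-subject tables correlate subject i's node A with every OTHER
subject's node B (and the reverse pairing, B_i with A_j), Fisher-transform
each correlation, and average the 2*(S-1) z-values into a single value per
subject and pair — the inter-subject-correlation analogue of seed
connectivity, which retains only stimulus-locked shared signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import HEMISPHERES, NETWORK_REGIONS, PairClass

log = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class NetworkLayout:
    """A named functional network: an ordered set of bilateral regions."""

    name: str
    regions: tuple[str, ...]
    hemispheres: tuple[str, str] = HEMISPHERES

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if len(self.regions) == 0:
            raise ValueError("a layout needs at least one region")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region names must be unique")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def nodes(self) -> list[tuple[str, str]]:
        """All (region, hemisphere) nodes, region-major, L before R."""
        return [(r, h) for r in self.regions for h in self.hemispheres]

    @classmethod
    def named(cls, name: str) -> "NetworkLayout":
        return cls(name=name, regions=NETWORK_REGIONS[name])


def node_label(region: str, hemisphere: str) -> str:
    return f"{region}_{hemisphere}"


@dataclass(frozen=True)
class PairInfo:
    node_a: tuple[str, str]
    node_b: tuple[str, str]
    pair_class: PairClass


def classify_pairs(layout: NetworkLayout) -> list[PairInfo]:
    """Label every unordered node pair with its comparison class."""
    nodes = layout.nodes
    pairs: list[PairInfo] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            (ra, ha), (rb, hb) = nodes[i], nodes[j]
            if ha == hb:
                cls = PairClass.INTRA
            elif ra == rb:
                cls = PairClass.INTER_CORRESPONDING
            else:
                cls = PairClass.INTER_NONCORRESPONDING
            pairs.append(PairInfo(nodes[i], nodes[j], cls))
    return pairs


def fisher_z(r, clip: bool = False):
    """Fisher's variance-stabilising transform ``Zr = atanh(r)``.

    ``|r| > 1`` is an input error.  ``|r| == 1`` is infinite under atanh:
    by default this raises; with ``clip=True`` the value is clipped to
    ``1 - 1e-7`` in magnitude (and the clip is logged).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    at_limit = np.abs(arr) == 1.0
    if np.any(at_limit):
        if not clip:
            raise ValueError("|r| = 1 gives infinite Zr; pass clip=True to clip")
        log.warning("clipped %d correlation(s) at |r| = 1", int(np.sum(at_limit)))
        arr = np.clip(arr, -_CLIP, _CLIP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


_COLUMNS = ["subject", "node_a", "node_b", "pair_class", "r", "Zr", "mode"]


def _check_dataset(dataset, layout: NetworkLayout) -> None:
    if tuple(dataset.regions) != layout.regions:
        raise ValueError(
            f"dataset regions {dataset.regions} do not match layout "
            f"{layout.regions}"
        )


def within_subject_table(dataset, layout: NetworkLayout, clip: bool = True) -> pd.DataFrame:
    """Per-subject Pearson/Fisher-z correlations for every node pair.

    Correlations run over the full concatenated series.  A pair touching a
    zero-variance series is kept as a row with NaN r/Zr (flagged missing,
    never silently zero).
    """
    _check_dataset(dataset, layout)
    if dataset.n_timepoints < 3:
        raise ValueError("need at least 3 time points for a correlation")
    pairs = classify_pairs(layout)
    nodes = layout.nodes
    node_index = {n: k for k, n in enumerate(nodes)}
    rows = []
    for s in range(dataset.n_subjects):
        mat = dataset.node_matrix(s)
        sd = mat.std(axis=1)
        degenerate = sd == 0
        if degenerate.any():
            log.warning("subject %d: %d zero-variance node series",
                        s, int(degenerate.sum()))
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(mat)
        for p in pairs:
            i, j = node_index[p.node_a], node_index[p.node_b]
            if degenerate[i] or degenerate[j]:
                r = np.nan
            else:
                r = float(np.clip(corr[i, j], -1.0, 1.0))
            zr = np.nan if np.isnan(r) else fisher_z(r, clip=clip)
            rows.append((s, node_label(*p.node_a), node_label(*p.node_b),
                         p.pair_class.value, r, zr, "within"))
    return pd.DataFrame(rows, columns=_COLUMNS)


def between_subject_table(dataset, layout: NetworkLayout, clip: bool = True,
                          average_space: str = "z") -> pd.DataFrame:
    """Between-subject connectivity: one averaged value per subject and pair.

    For subject ``i`` and node pair (A, B), the 2*(S-1) cross-subject
    correlations ``r(A_i, B_j)`` and ``r(B_i, A_j)`` (all ``j != i``) are
    Fisher-transformed and averaged in z-space (``average_space="z"``,
    default) or averaged as r then transformed (``average_space="r"``, for
    sensitivity checks).
    """
    _check_dataset(dataset, layout)
    if dataset.n_subjects < 2:
        raise ValueError("between-subject analysis needs at least 2 subjects")
    if average_space not in ("z", "r"):
        raise ValueError("average_space must be 'z' or 'r'")
    pairs = classify_pairs(layout)
    nodes = layout.nodes
    node_index = {n: k for k, n in enumerate(nodes)}
    S, n_nodes = dataset.n_subjects, len(nodes)
    T = dataset.n_timepoints

    # Full (S * n_nodes) x (S * n_nodes) correlation matrix; row s*n_nodes+k
    # is subject s's node k.
    stacked = dataset.data.reshape(S * n_nodes, T)
    sd = stacked.std(axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(stacked)

    def cross(i, k_a, j, k_b):
        if sd[i * n_nodes + k_a] == 0 or sd[j * n_nodes + k_b] == 0:
            return np.nan
        return float(np.clip(corr[i * n_nodes + k_a, j * n_nodes + k_b], -1.0, 1.0))

    rows = []
    for i in range(S):
        for p in pairs:
            ka, kb = node_index[p.node_a], node_index[p.node_b]
            rs = []
            for j in range(S):
                if j == i:
                    continue
                rs.append(cross(i, ka, j, kb))
                rs.append(cross(i, kb, j, ka))
            rs = np.asarray(rs, dtype=float)
            valid = ~np.isnan(rs)
            if not valid.any():
                r_avg, zr = np.nan, np.nan
            elif average_space == "z":
                zr = float(np.mean(fisher_z(rs[valid], clip=clip)))
                r_avg = float(np.tanh(zr))
            else:
                r_avg = float(np.mean(rs[valid]))
                zr = fisher_z(r_avg, clip=clip)
            rows.append((i, node_label(*p.node_a), node_label(*p.node_b),
                         p.pair_class.value, r_avg, zr, "between"))
    return pd.DataFrame(rows, columns=_COLUMNS)


# ---------------------------------------------------------------------------
# Per-region summaries


SUMMARY_FIELDS = (
    "inter_corresponding_Zr",
    "intra_avg_Zr",
    "intra_high_Zr",
    "inter_noncorr_avg_Zr",
    "inter_noncorr_high_Zr",
)


def _pairs_involving(table: pd.DataFrame, region: str, pair_class: PairClass) -> pd.DataFrame:
    labels = {node_label(region, h) for h in HEMISPHERES}
    sel = table["pair_class"] == pair_class.value
    sel &= table["node_a"].isin(labels) | table["node_b"].isin(labels)
    return table[sel]


def region_summary(table: pd.DataFrame, region: str,
                   selection: str = "group") -> pd.DataFrame:
    """Per-subject summary of a region's pairing-class z-values.

    Columns: ``inter_corresponding_Zr`` (the region's homotopic pair);
    ``intra_avg_Zr`` (mean over ALL intrahemispheric pairs involving either
    hemisphere's copy of the region — both hemispheres pooled);
    ``intra_high_Zr`` (the single intra pairing with the highest group-mean
    Zr, selected once per dataset and applied to every subject); and the
    same two summaries over non-corresponding interhemispheric pairs.

    ``selection="subject"`` instead takes each subject's own maximum pair
    (sensitivity option; upward-biased by construction).

    A single-region layout has no intra or non-corresponding pairs; those
    columns are NaN and a warning is logged.
    """
    if selection not in ("group", "subject"):
        raise ValueError("selection must be 'group' or 'subject'")
    label_l, label_r = (node_label(region, h) for h in HEMISPHERES)
    inter = table[
        (table["pair_class"] == PairClass.INTER_CORRESPONDING.value)
        & (
            (table["node_a"].isin([label_l, label_r]))
            & (table["node_b"].isin([label_l, label_r]))
        )
    ]
    if inter.empty:
        raise ValueError(f"region {region!r} not present in the table")
    out = inter.set_index("subject")[["Zr"]].rename(
        columns={"Zr": "inter_corresponding_Zr"}
    )

    for cls, avg_col, high_col in (
        (PairClass.INTRA, "intra_avg_Zr", "intra_high_Zr"),
        (PairClass.INTER_NONCORRESPONDING, "inter_noncorr_avg_Zr", "inter_noncorr_high_Zr"),
    ):
        sub = _pairs_involving(table, region, cls)
        if sub.empty:
            log.warning("region %s has no %s pairs (single-region layout?)",
                        region, cls.value)
            out[avg_col] = np.nan
            out[high_col] = np.nan
            out[high_col + "_pair"] = ""
            continue
        pair_key = sub["node_a"] + ":" + sub["node_b"]
        sub = sub.assign(pair=pair_key.values)
        out[avg_col] = sub.groupby("subject")["Zr"].mean()
        if selection == "group":
            best_pair = sub.groupby("pair")["Zr"].mean().idxmax()
            best = sub[sub["pair"] == best_pair].set_index("subject")["Zr"]
            out[high_col] = best
            out[high_col + "_pair"] = best_pair
        else:
            idx = sub.groupby("subject")["Zr"].idxmax()
            best = sub.loc[idx].set_index("subject")
            out[high_col] = best["Zr"]
            out[high_col + "_pair"] = best["pair"]
    out.insert(0, "region", region)
    return out.reset_index()
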