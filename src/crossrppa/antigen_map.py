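"""Clustered antibody antigen map and cross-platform concordance scoring.

The antigen map is a matrix with clustered antibody measurement columns
(in dendrogram leaf order) as columns and alphabetically ordered antigen
classes as rows.  The single filled cell in each column holds the integer
index of that column's antibody within its antigen class (distinct
antibody uids enumerated from 1 in sorted-uid order), so different shades
in the rendered heatmap distinguish different antibodies against the same
antigen.

Concordance scoring asks, per antigen class, whether any of its antibody
columns clusters with a same-class column measured (a) on another
platform and (b) by a different antibody.  "Clusters with" defaults to
the sibling-subtree rule: the companions of a leaf are the leaves of the
sibling subtree at its parent merge node.  A k-nearest-cophenetic-
neighbour rule is available as an alternative.  Because the percentages
depend on this membership rule, eligibility denominators are always
reported alongside the fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import Dendrogram
from .exceptions import AnnotationError, ConfigError

__all__ = [
    "AntigenMapMatrix",
    "ConcordanceReport",
    "antibody_indices",
    "build_antigen_map",
    "score_concordance",
]

RULES = ("sibling", "k_cophenetic_neighbours")


@dataclass
class AntigenMapMatrix:
    """Integer-indexed antibody map; 0 encodes an empty cell."""

    frame: pd.DataFrame  # rows: antigen classes (alphabetical); columns: leaf order

    def to_tsv(self, path) -> None:
        out = self.frame.replace(0, np.nan)
        out.to_csv(path, sep="\t", float_format="%d", na_rep="")


def antibody_indices(column_annotations: pd.DataFrame) -> dict[str, int]:
    """Fixed integer index per antibody uid within its antigen class.

    Distinct uids of each class are sorted and enumerated from 1; the
    index is a property of the antibody, independent of clustering.
    """
    idx: dict[str, int] = {}
    for _, grp in column_annotations.groupby("antigen_class"):
        for i, uid in enumerate(sorted(grp["antibody_uid"].unique()), start=1):
            idx[uid] = i
    return idx


def build_antigen_map(
    leaf_order: list[str], column_annotations: pd.DataFrame
) -> AntigenMapMatrix:
    """Expand clustered antibody columns into the antigen-class map matrix.

    ``leaf_order`` lists measurement-column labels in clustered order;
    ``column_annotations`` (indexed by those labels) supplies antibody_uid
    and antigen_class per column.  Every column gets exactly one filled
    cell: its antibody's integer index in the row of its antigen class.
    """
    unknown = [l for l in leaf_order if l not in column_annotations.index]
    if unknown:
        raise AnnotationError(f"unannotated antibody column(s): {unknown[:5]}")
    ann = column_annotations.loc[leaf_order]
    classes = sorted(ann["antigen_class"].unique())
    index_of = antibody_indices(column_annotations)
    M = pd.DataFrame(0, index=classes, columns=leaf_order, dtype=int)
    for col, rec in ann.iterrows():
        M.loc[rec["antigen_class"], col] = index_of[rec["antibody_uid"]]
    M.index.name = "antigen_class"
    return AntigenMapMatrix(frame=M)


@dataclass
class ConcordanceReport:
    """Per-class concordance flags and the two summary fractions."""

    per_class: pd.DataFrame
    rule: str
    cross_platform_fraction: float
    cross_platform_eligible: int
    cross_antibody_fraction: float
    cross_antibody_eligible: int

    def summary(self) -> dict:
        return {
            "rule": self.rule,
            "cross_platform_fraction": self.cross_platform_fraction,
            "cross_platform_eligible": self.cross_platform_eligible,
            "cross_antibody_fraction": self.cross_antibody_fraction,
            "cross_antibody_eligible": self.cross_antibody_eligible,
        }


def _companions_sibling(dend: Dendrogram) -> dict[int, list[int]]:
    ps = dend.parent_and_sibling()
    return {
        leaf: dend.node_members(ps[leaf][1]) if leaf in ps else []
        for leaf in range(dend.n_leaves)
    }


def _companions_cophenetic(dend: Dendrogram, k: int) -> dict[int, list[int]]:
    C = dend.cophenetic_matrix()
    out = {}
    for leaf in range(dend.n_leaves):
        others = [(C[leaf, j], dend.labels[j], j) for j in range(dend.n_leaves) if j != leaf]
        others.sort()
        out[leaf] = [j for _, _, j in others[:k]]
    return out


def score_concordance(
    dend: Dendrogram,
    column_annotations: pd.DataFrame,
    rule: str = "sibling",
    k: int = 3,
) -> ConcordanceReport:
    """Score per-antigen-class clustering concordance on a column dendrogram.

    A class is cross-platform concordant if any of its columns has, among
    its companions under the chosen rule, a same-class column from a
    different platform; cross-antibody concordant likewise with a
    different antibody uid.  Classes measured on fewer than two platforms
    (respectively with fewer than two distinct uids) are excluded from the
    corresponding denominator.
    """
    if rule not in RULES:
        raise ConfigError(f"unknown concordance rule {rule!r}; choose from {RULES}")
    missing = [l for l in dend.labels if l not in column_annotations.index]
    if missing:
        raise AnnotationError(f"unannotated leaf column(s): {missing[:5]}")
    ann = column_annotations.loc[dend.labels]
    klass = ann["antigen_class"].to_numpy()
    uid = ann["antibody_uid"].to_numpy()
    platform = ann["platform_id"].to_numpy()

    companions = (
        _companions_sibling(dend)
        if rule == "sibling"
        else _companions_cophenetic(dend, k)
    )

    rows = []
    for c in sorted(set(klass)):
        cols = np.where(klass == c)[0]
        n_platforms = len(set(platform[cols]))
        n_uids = len(set(uid[cols]))
        plat_hit = ab_hit = False
        for leaf in cols:
            for comp in companions[leaf]:
                if klass[comp] != c:
                    continue
                if platform[comp] != platform[leaf]:
                    plat_hit = True
                if uid[comp] != uid[leaf]:
                    ab_hit = True
        rows.append(
            {
                "antigen_class": c,
                "n_columns": len(cols),
                "n_platforms": n_platforms,
                "n_antibodies": n_uids,
                "cross_platform_eligible": n_platforms >= 2,
                "cross_platform_concordant": bool(plat_hit) if n_platforms >= 2 else False,
                "cross_antibody_eligible": n_uids >= 2,
                "cross_antibody_concordant": bool(ab_hit) if n_uids >= 2 else False,
            }
        )
    per_class = pd.DataFrame(rows).set_index("antigen_class")
    pe = per_class[per_class["cross_platform_eligible"]]
    ae = per_class[per_class["cross_antibody_eligible"]]
    return ConcordanceReport(
        per_class=per_class,
        rule=rule,
        cross_platform_fraction=float(pe["cross_platform_concordant"].mean()) if len(pe) else np.nan,
        cross_platform_eligible=int(len(pe)),
        cross_antibody_fraction=float(ae["cross_antibody_concordant"].mean()) if len(ae) else np.nan,
        cross_antibody_eligible=int(len(ae)),
    )
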