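"""Cross-platform dataset integration.

Assigns canonical antigen classes and unique antibody identifiers,
median-centres each platform's log2 matrix antibody-wise, horizontally
concatenates the platforms, and filters to antigen classes measured on
every platform.  Median centring places platforms on a common relative
scale; no further batch correction is applied.  Missing values are
carried, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, AnnotationError
from .processing import ProcessedIntensityMatrix

__all__ = [
    "classify_antigens",
    "assign_antibody_uids",
    "annotate_panels",
    "median_centre",
    "IntegratedMatrix",
    "integrate",
    "column_label",
]


def classify_antigens(
    targets_by_antibody: Mapping[object, Sequence[str]],
    synonyms: Mapping[str, str] | None = None,
) -> dict[object, str]:
    """Map each antibody's declared target(s) to one canonical antigen class.

    An antibody may recognise a protein together with one close isoform or
    family member; the synonym table must merge such pairs into a single
    canonical class (e.g. Erk1 and Erk1/2 -> Erk1/2).  Targets that still
    resolve to more than one class are an unresolved-class error.
    """
    synonyms = synonyms or {}
    classes: dict[object, str] = {}
    for key, targets in targets_by_antibody.items():
        targets = list(targets)
        if not targets:
            raise AnnotationError(f"antibody {key!r} declares no target")
        canonical = {synonyms.get(t, t) for t in targets}
        if len(canonical) != 1:
            raise AnnotationError(
                f"antibody {key!r} targets {targets!r} resolve to multiple antigen "
                f"classes {sorted(canonical)}; add a synonym rule to merge them"
            )
        classes[key] = canonical.pop()
    return classes


def _letter(i: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa, ..."""
    out = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def assign_antibody_uids(annotations: pd.DataFrame) -> pd.DataFrame:
    """Assign unique antibody identifiers (antigen class + letter suffix).

    Within each antigen class, distinct supplier references are enumerated
    a, b, c, ... in sorted supplier-reference order, so the assignment is
    deterministic and identical supplier references shared by several
    platforms receive the same uid.  Requires columns platform_id,
    antibody_id, antigen_class, supplier_ref, phospho_site.
    """
    required = {"platform_id", "antibody_id", "antigen_class", "supplier_ref"}
    missing = required - set(annotations.columns)
    if missing:
        raise AnnotationError(f"annotation table lacks columns {sorted(missing)}")
    ann = annotations.copy()
    if "phospho_site" not in ann.columns:
        ann["phospho_site"] = ""

    # a physical antibody (supplier_ref) must map to exactly one class/site
    for ref, grp in ann.groupby("supplier_ref"):
        if grp["antigen_class"].nunique() > 1:
            raise AnnotationError(
                f"supplier_ref {ref!r} maps to conflicting antigen classes "
                f"{sorted(grp['antigen_class'].unique())}"
            )
        if grp["phospho_site"].nunique() > 1:
            raise AnnotationError(
                f"supplier_ref {ref!r} carries conflicting phospho-site annotations "
                f"{sorted(grp['phospho_site'].unique())}"
            )

    uid_of: dict[tuple[str, str], str] = {}
    for antigen, grp in ann.groupby("antigen_class"):
        for i, ref in enumerate(sorted(grp["supplier_ref"].unique())):
            uid_of[(antigen, ref)] = f"{antigen}_{_letter(i)}"
    ann["antibody_uid"] = [
        uid_of[(c, r)] for c, r in zip(ann["antigen_class"], ann["supplier_ref"])
    ]
    return ann


def annotate_panels(
    raw_annotations: pd.DataFrame, synonyms: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Raw panel annotations -> classified, uid-assigned annotation table.

    ``raw_annotations`` must hold platform_id, antibody_id, targets
    (";"-separated declared targets), supplier_ref and phospho_site.
    """
    ann = raw_annotations.copy()
    targets = {
        i: str(t).split(";") for i, t in zip(ann.index, ann["targets"])
    }
    classes = classify_antigens(targets, synonyms)
    ann["antigen_class"] = [classes[i] for i in ann.index]
    return assign_antibody_uids(ann.drop(columns=["targets"]))


def median_centre(matrix: pd.DataFrame, subset: Iterable | None = None) -> pd.DataFrame:
    """Subtract each column's median; missing entries are untouched.

    ``subset`` optionally names the rows (samples) over which medians are
    computed; centring is then applied to every row.  Columns with no
    observed value in the centring subset are dropped with a warning.
    """
    ref = matrix if subset is None else matrix.loc[list(subset)]
    medians = ref.median(axis=0, skipna=True)
    dead = medians.index[medians.isna()]
    if len(dead):
        warnings.warn(
            f"dropping {len(dead)} all-missing column(s): {list(dead)[:5]}",
            stacklevel=2,
        )
        matrix = matrix.drop(columns=dead)
        medians = medians.drop(dead)
    return matrix.sub(medians, axis=1)


def column_label(antibody_uid: str, platform_id: str) -> str:
    """Flat column label for one antibody-platform measurement column."""
    return f"{antibody_uid}@{platform_id}"


@dataclass
class IntegratedMatrix:
    """Median-centred, horizontally concatenated multi-platform matrix.

    Columns are flat "uid@platform" labels; ``column_annotations`` (indexed
    by those labels) records antibody_uid, platform_id, antigen_class,
    supplier_ref and phospho_site per column.  ``manifest`` records dropped
    antigen classes, per-platform reading counts and the centring subset.
    """

    values: pd.DataFrame
    column_annotations: pd.DataFrame
    manifest: dict

    @property
    def n_readings(self) -> int:
        return int(self.values.shape[0] * self.values.shape[1])


def integrate(
    matrices: Sequence[ProcessedIntensityMatrix],
    annotations: pd.DataFrame,
    centring_samples: Iterable | None = None,
) -> IntegratedMatrix:
    """Median-centre per platform, concatenate, and apply the all-platform filter.

    Antigen classes not measured on every supplied platform are removed
    entirely.  All platforms must carry the same sample set.  When
    ``centring_samples`` is given, column medians are computed over that
    subset only (e.g. vehicle controls) and subtracted from all samples.
    """
    if not matrices:
        raise AlignmentError("no platform matrices supplied")
    ref_index = matrices[0].values.index
    for m in matrices[1:]:
        missing = set(ref_index) ^ set(m.values.index)
        if missing:
            raise AlignmentError(
                f"platform {m.platform_id!r} sample set differs from "
                f"{matrices[0].platform_id!r}; mismatched samples: {sorted(missing)[:6]}"
            )

    ann = annotations.set_index(["platform_id", "antibody_id"])
    classes_per_platform: list[set[str]] = []
    for m in matrices:
        covered = []
        for ab in m.values.columns:
            key = (m.platform_id, ab)
            if key not in ann.index:
                raise AnnotationError(
                    f"no annotation for antibody {ab!r} on platform {m.platform_id!r}"
                )
            covered.append(ann.loc[key, "antigen_class"])
        classes_per_platform.append(set(covered))
    retained_classes = set.intersection(*classes_per_platform)
    dropped_classes = sorted(set.union(*classes_per_platform) - retained_classes)

    blocks, col_rows, per_platform = [], [], {}
    centring = list(centring_samples) if centring_samples is not None else None
    for m in matrices:
        keep, rows = [], []
        for ab in m.values.columns:
            rec = ann.loc[(m.platform_id, ab)]
            if rec["antigen_class"] not in retained_classes:
                continue
            keep.append(ab)
            rows.append(
                {
                    "column": column_label(rec["antibody_uid"], m.platform_id),
                    "antibody_uid": rec["antibody_uid"],
                    "platform_id": m.platform_id,
                    "antibody_id": ab,
                    "antigen_class": rec["antigen_class"],
                    "supplier_ref": rec["supplier_ref"],
                    "phospho_site": rec.get("phospho_site", ""),
                }
            )
        block = m.values.loc[ref_index, keep]
        block = median_centre(block, subset=centring)
        block.columns = [r["column"] for r in rows]
        blocks.append(block)
        col_rows.extend(rows)
        per_platform[m.platform_id] = {
            "method": m.method,
            "n_columns": len(keep),
            "n_readings": int(block.shape[0] * block.shape[1]),
        }

    values = pd.concat(blocks, axis=1)
    col_ann = pd.DataFrame(col_rows).set_index("column")
    manifest = {
        "n_samples": int(values.shape[0]),
        "n_columns": int(values.shape[1]),
        "n_readings": int(values.shape[0] * values.shape[1]),
        "platforms": per_platform,
        "dropped_antigen_classes": dropped_classes,
        "retained_antigen_classes": sorted(retained_classes),
        "centring_samples": "all" if centring is None else len(centring),
    }
    return IntegratedMatrix(values=values, column_annotations=col_ann, manifest=manifest)
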