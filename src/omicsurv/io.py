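"""Readers/writers for the cohort file set and the validated `CohortBundle`.

File formats (all TSV, UTF-8, tab-delimited, no quoting, header row):

* segments:    ``sample  chrom  start  end  log2_ratio`` — per-sample copy
  number segments; coordinates are 1-based, fully-closed intervals (SEG
  convention).
* annotation:  ``gene  chrom  start  end`` — gene intervals, same convention.
* methylation: samples as rows, genes as columns, leading ``sample`` column;
  beta values in [0, 1].
* expression:  same orientation; non-negative values, missing encoded ``NA``
  (missing and exact zeros are both "null" for downstream filtering).
* clinical:    ``sample  time_days  event  metastasis`` — survival time in
  days (>= 0), event indicator 1 = death observed / 0 = censored, metastasis
  or relapse flag ``yes``/``no``.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from omicsurv.exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio"]
ANNOTATION_COLUMNS = ["gene", "chrom", "start", "end"]
CLINICAL_COLUMNS = ["time_days", "event", "metastasis"]

FILE_NAMES = {
    "segments": "segments.tsv",
    "annotation": "annotation.tsv",
    "methylation": "methylation.tsv",
    "expression": "expression.tsv",
    "clinical": "clinical.tsv",
}


class CohortBundle:
    """The three omics layers plus clinical data for one ordered sample set.

    ``methylation`` and ``expression`` are samples x genes DataFrames;
    ``segments`` and ``annotation`` are long-form record tables; ``clinical``
    is indexed by sample. All layers and the clinical table share an
    identical, ordered sample index.
    """

    def __init__(
        self,
        segments: pd.DataFrame,
        annotation: pd.DataFrame,
        methylation: pd.DataFrame,
        expression: pd.DataFrame,
        clinical: pd.DataFrame,
        validate: bool = True,
    ) -> None:
        self.segments = segments
        self.annotation = annotation
        self.methylation = methylation
        self.expression = expression
        self.clinical = clinical
        if validate:
            self.validate()

    @property
    def samples(self) -> pd.Index:
        return self.clinical.index

    def validate(self) -> None:
        samples = self.clinical.index
        if samples.duplicated().any():
            raise ValidationError("clinical: duplicated sample ids")
        for name, frame in (("methylation", self.methylation), ("expression", self.expression)):
            if not frame.index.equals(samples):
                raise ValidationError(
                    f"{name}: sample index differs from the clinical table"
                )
        unknown = set(self.segments["sample"]) - set(samples)
        if unknown:
            raise ValidationError(
                f"segments: unknown sample ids {sorted(unknown)[:5]}"
            )
        _validate_segments(self.segments)
        _validate_annotation(self.annotation)
        _validate_methylation_values(self.methylation)
        _validate_expression_values(self.expression)
        _validate_clinical_values(self.clinical)

    def equals(self, other: "CohortBundle") -> bool:
        try:
            pd.testing.assert_frame_equal(
                self.segments.reset_index(drop=True),
                other.segments.reset_index(drop=True),
            )
            pd.testing.assert_frame_equal(
                self.annotation.reset_index(drop=True),
                other.annotation.reset_index(drop=True),
            )
            pd.testing.assert_frame_equal(self.methylation, other.methylation)
            pd.testing.assert_frame_equal(self.expression, other.expression)
            pd.testing.assert_frame_equal(self.clinical, other.clinical)
        except AssertionError:
            return False
        return True


# ---------------------------------------------------------------------------
# validation helpers

def _validate_segments(seg: pd.DataFrame) -> None:
    missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
    if missing:
        raise ValidationError(f"segments: missing columns {missing}")
    if len(seg) and (seg["start"] > seg["end"]).any():
        bad = seg.loc[seg["start"] > seg["end"]].iloc[0]
        raise ValidationError(
            f"segments: start > end for sample {bad['sample']} at {bad['chrom']}:{bad['start']}"
        )
    if len(seg) and not np.isfinite(seg["log2_ratio"].to_numpy(float)).all():
        raise ValidationError("segments: non-finite log2 ratio")


def _validate_annotation(ann: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation: missing columns {missing}")
    if ann["gene"].duplicated().any():
        dup = ann.loc[ann["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"annotation: duplicated gene symbol {dup!r}")
    if len(ann) and (ann["start"] > ann["end"]).any():
        raise ValidationError("annotation: start > end")


def _validate_methylation_values(meth: pd.DataFrame) -> None:
    values = meth.to_numpy(float)
    with np.errstate(invalid="ignore"):
        bad = (values < 0.0) | (values > 1.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"methylation: beta value {values[i, j]!r} outside [0, 1] "
            f"for gene {meth.columns[j]!r}, sample {meth.index[i]!r}"
        )


def _validate_expression_values(expr: pd.DataFrame) -> None:
    values = expr.to_numpy(float)
    with np.errstate(invalid="ignore"):
        bad = values < 0.0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"expression: negative value for gene {expr.columns[j]!r}, "
            f"sample {expr.index[i]!r}"
        )


def _validate_clinical_values(clin: pd.DataFrame) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing:
        raise ValidationError(f"clinical: missing columns {missing}")
    if clin["time_days"].isna().any() or clin["event"].isna().any():
        sample = clin.index[clin["time_days"].isna() | clin["event"].isna()][0]
        raise ValidationError(f"clinical: missing survival time/event for sample {sample!r}")
    if (clin["time_days"] < 0).any():
        raise ValidationError("clinical: negative survival time")
    if not clin["event"].isin((0, 1)).all():
        raise ValidationError("clinical: event indicator must be 0 or 1")
    if not clin["metastasis"].isin(("yes", "no")).all():
        raise ValidationError("clinical: metastasis flag must be 'yes' or 'no'")


# ---------------------------------------------------------------------------
# readers

def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    except FileNotFoundError as exc:
        raise ParseError(f"{path}: file not found") from exc


def _numeric(frame: pd.DataFrame, columns: list[str], path: Path) -> pd.DataFrame:
    for col in columns:
        try:
            frame[col] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{path}, line {line}: malformed numeric field in column {col!r}") from exc
    return frame


def read_segments(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    seg = _read_tsv(path)
    missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    seg = _numeric(seg, ["start", "end", "log2_ratio"], path)
    seg["start"] = seg["start"].astype(np.int64)
    seg["end"] = seg["end"].astype(np.int64)
    _validate_segments(seg)
    return seg[SEGMENT_COLUMNS]


def read_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    ann = _read_tsv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    ann = _numeric(ann, ["start", "end"], path)
    ann["start"] = ann["start"].astype(np.int64)
    ann["end"] = ann["end"].astype(np.int64)
    _validate_annotation(ann)
    return ann[ANNOTATION_COLUMNS]


def read_matrix(path: str | Path, layer: str) -> pd.DataFrame:
    """Read a samples x genes matrix; ``layer`` selects the value-domain check."""
    path = Path(path)
    frame = _read_tsv(path)
    if frame.columns[0] != "sample":
        raise ParseError(f"{path}: first column must be 'sample'")
    frame = frame.set_index("sample")
    for col in frame.columns:
        try:
            frame[col] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: malformed numeric field in column {col!r}") from exc
    frame = frame.astype(float)
    if layer == "methylation":
        _validate_methylation_values(frame)
    elif layer == "expression":
        _validate_expression_values(frame)
    return frame


def read_clinical(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    clin = _read_tsv(path)
    if "sample" not in clin.columns:
        raise ParseError(f"{path}: missing 'sample' column")
    clin = clin.set_index("sample")
    clin = _numeric(clin.reset_index(), ["time_days", "event"], path).set_index("sample")
    clin["time_days"] = clin["time_days"].astype(float)
    clin["event"] = clin["event"].astype(np.int64)
    _validate_clinical_values(clin)
    return clin[CLINICAL_COLUMNS]


def load_cohort(source: str | Path | dict[str, str | Path]) -> CohortBundle:
    """Assemble a validated bundle from a directory or an explicit path map.

    Sample sets of the matrices, the clinical table and the segment file are
    intersected; dropped samples are reported via a warning. Disjoint sample
    sets are a hard error.
    """
    if isinstance(source, (str, Path)):
        directory = Path(source)
        paths = {k: directory / v for k, v in FILE_NAMES.items()}
    else:
        paths = {k: Path(v) for k, v in source.items()}

    segments = read_segments(paths["segments"])
    annotation = read_annotation(paths["annotation"])
    methylation = read_matrix(paths["methylation"], "methylation")
    expression = read_matrix(paths["expression"], "expression")
    clinical = read_clinical(paths["clinical"])

    sets = {
        "methylation": set(methylation.index),
        "expression": set(expression.index),
        "clinical": set(clinical.index),
        "segments": set(segments["sample"]),
    }
    shared = sets["methylation"] & sets["expression"] & sets["clinical"] & sets["segments"]
    if not shared:
        raise ValidationError("load_cohort: sample sets of the input files are disjoint")
    dropped = sorted(set().union(*sets.values()) - shared)
    if dropped:
        msg = f"load_cohort: dropping {len(dropped)} sample(s) absent from some file: {dropped[:10]}"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
    order = sorted(shared)
    bundle = CohortBundle(
        segments=segments[segments["sample"].isin(shared)].reset_index(drop=True),
        annotation=annotation,
        methylation=methylation.loc[order],
        expression=expression.loc[order],
        clinical=clinical.loc[order],
    )
    return bundle


# ---------------------------------------------------------------------------
# writers

def write_bundle(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write the five cohort files; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FILE_NAMES.items()}
    bundle.segments.to_csv(paths["segments"], sep="\t", index=False)
    bundle.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    bundle.methylation.to_csv(paths["methylation"], sep="\t", index=True, index_label="sample", na_rep="NA")
    bundle.expression.to_csv(paths["expression"], sep="\t", index=True, index_label="sample", na_rep="NA")
    bundle.clinical.to_csv(paths["clinical"], sep="\t", index=True, index_label="sample")
    return paths
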