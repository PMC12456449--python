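"""Observed-data containers, CSV input/output, and double-zero filtering.

The atomic unit is one study's two-arm 2x2 margin: event counts ``y1``
(treated) and ``y2`` (control) out of ``n1`` and ``n2`` subjects.  A
*double-zero* (DZ) study has no events in either arm; under the
conditional model (events in the treated arm given the study's total
events) such studies carry no information about the relative risk and are
removed before analysis.  No continuity correction is offered for DZ
studies: the conditional argument makes them uninformative rather than
merely awkward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = ("y1", "n1", "y2", "n2")

_EXAMPLES = {
    "rosiglitazone_mi": "rosiglitazone_mi_synthetic.csv",
    "rosiglitazone_cvd": "rosiglitazone_cvd_synthetic.csv",
    "facemask": "facemask_synthetic.csv",
}


class DataError(ValueError):
    """Malformed or inconsistent study-level count data."""


class AllDoubleZeroError(DataError):
    """Every study in the input is double-zero; nothing to analyse."""


@dataclass(frozen=True)
class StudyCounts:
    """Two-arm event counts for one study.

    Arm 1 is the treated arm by convention; swapping the arms reflects
    the treatment contrast around 0.5.
    """

    y1: int
    n1: int
    y2: int
    n2: int
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("y1", "n1", "y2", "n2"):
            val = getattr(self, name)
            if not float(val).is_integer():
                raise DataError(f"{name}={val!r} is not an integer")
            object.__setattr__(self, name, int(val))
        if self.n1 < 1 or self.n2 < 1:
            raise DataError(f"sample sizes must be >= 1, got n1={self.n1}, n2={self.n2}")
        if not (0 <= self.y1 <= self.n1):
            raise DataError(f"need 0 <= y1 <= n1, got y1={self.y1}, n1={self.n1}")
        if not (0 <= self.y2 <= self.n2):
            raise DataError(f"need 0 <= y2 <= n2, got y2={self.y2}, n2={self.n2}")

    @property
    def y_total(self) -> int:
        """Total events across both arms (the conditioning statistic)."""
        return self.y1 + self.y2

    @property
    def is_double_zero(self) -> bool:
        return self.y_total == 0

    @property
    def is_balanced(self) -> bool:
        return self.n1 == self.n2

    @property
    def offset(self) -> float:
        """Design offset ``log(n1 / n2)``; zero iff the design is balanced."""
        return float(np.log(self.n1 / self.n2))


def filter_double_zero(
    studies: Iterable[StudyCounts],
) -> tuple[list[StudyCounts], int]:
    """Drop double-zero studies, preserving order.

    Returns the retained studies and the number removed.  Idempotent; an
    empty result is legal here (downstream operations reject it).
    """
    studies = list(studies)
    retained = [s for s in studies if not s.is_double_zero]
    return retained, len(studies) - len(retained)


@dataclass(frozen=True)
class MetaDataset:
    """Ordered collection of non-double-zero studies.

    ``studies`` holds only the retained (non-DZ) studies; ``k_tot`` is the
    study count before filtering, so ``k_tot - k`` is the number of DZ
    studies that were dropped.
    """

    studies: tuple[StudyCounts, ...]
    k_tot: int = field(default=-1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        if any(s.is_double_zero for s in self.studies):
            raise DataError("MetaDataset may not contain double-zero studies")
        if self.k_tot < 0:
            object.__setattr__(self, "k_tot", len(self.studies))
        if self.k_tot < len(self.studies):
            raise DataError("k_tot cannot be smaller than the number of retained studies")

    @classmethod
    def from_studies(cls, studies: Iterable[StudyCounts]) -> "MetaDataset":
        """Build a dataset from raw studies, filtering double-zero rows."""
        studies = list(studies)
        retained, n_removed = filter_double_zero(studies)
        if not retained:
            raise AllDoubleZeroError("all studies are double-zero; no information on the contrast")
        if n_removed:
            logger.info("removed %d double-zero studies (%d retained)", n_removed, len(retained))
        return cls(studies=tuple(retained), k_tot=len(studies))

    @property
    def k(self) -> int:
        """Number of retained studies."""
        return len(self.studies)

    @property
    def n_removed(self) -> int:
        return self.k_tot - self.k

    # Array views used by the numerical code.
    @property
    def y1(self) -> np.ndarray:
        return np.array([s.y1 for s in self.studies], dtype=np.int64)

    @property
    def y2(self) -> np.ndarray:
        return np.array([s.y2 for s in self.studies], dtype=np.int64)

    @property
    def n1(self) -> np.ndarray:
        return np.array([s.n1 for s in self.studies], dtype=np.int64)

    @property
    def n2(self) -> np.ndarray:
        return np.array([s.n2 for s in self.studies], dtype=np.int64)

    @property
    def y_total(self) -> np.ndarray:
        return self.y1 + self.y2

    @property
    def offsets(self) -> np.ndarray:
        """Per-study design offsets ``S_i = log(n1_i / n2_i)``."""
        return np.log(self.n1 / self.n2)

    @property
    def any_unbalanced(self) -> bool:
        return any(not s.is_balanced for s in self.studies)

    def swap_arms(self) -> "MetaDataset":
        """Exchange treated and control arms (reflects the contrast about 0.5)."""
        swapped = tuple(
            StudyCounts(y1=s.y2, n1=s.n2, y2=s.y1, n2=s.n1, label=s.label) for s in self.studies
        )
        return MetaDataset(studies=swapped, k_tot=self.k_tot)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [s.label for s in self.studies],
                "y1": self.y1,
                "n1": self.n1,
                "y2": self.y2,
                "n2": self.n2,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_meta_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> MetaDataset:
    """Read study-level counts from CSV and drop double-zero studies.

    Parameters
    ----------
    path
        CSV file with a header row, one study per row.
    column_map
        Optional mapping from the canonical names ``y1, n1, y2, n2``
        (and optionally ``label``) to the file's column names.  Extra
        columns are ignored.  Arm 1 is the treated arm; to reverse the
        contrast, map ``y1/n1`` to the control columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    frame = pd.read_csv(path)
    cmap = {name: name for name in DEFAULT_COLUMNS}
    cmap["label"] = "label"
    if column_map:
        unknown = set(column_map) - set(cmap)
        if unknown:
            raise DataError(f"unknown column-map keys: {sorted(unknown)}")
        cmap.update(column_map)
    missing = [cmap[c] for c in DEFAULT_COLUMNS if cmap[c] not in frame.columns]
    if missing:
        raise DataError(f"{path.name}: missing required columns {missing}")
    has_label = cmap["label"] in frame.columns

    studies = []
    for idx, row in frame.iterrows():
        values = {}
        for canon in DEFAULT_COLUMNS:
            raw = row[cmap[canon]]
            try:
                fval = float(raw)
            except (TypeError, ValueError):
                raise DataError(f"{path.name} row {idx + 1}: cannot parse {cmap[canon]}={raw!r}")
            if not np.isfinite(fval) or fval != int(fval) or fval < 0:
                raise DataError(
                    f"{path.name} row {idx + 1}: {cmap[canon]}={raw!r} is not a non-negative integer"
                )
            values[canon] = int(fval)
        label = str(row[cmap["label"]]) if has_label else f"study_{idx + 1}"
        try:
            studies.append(StudyCounts(label=label, **values))
        except DataError as err:
            raise DataError(f"{path.name} row {idx + 1}: {err}") from err
    if not studies:
        raise DataError(f"{path.name}: no data rows")
    return MetaDataset.from_studies(studies)


def load_example(name: str) -> MetaDataset:
    """Load a packaged example dataset.

    Available names: ``rosiglitazone_mi``, ``rosiglitazone_cvd``,
    ``facemask``.  These are *synthetic stand-ins*: model-generated
    tables that mimic the shape of the published rare-event
    meta-analyses (study count, sample-size spread, double-zero
    prevalence) but are not the published study data, so results
    computed from them do not reproduce any published analysis.
    """
    try:
        filename = _EXAMPLES[name]
    except KeyError:
        raise KeyError(f"unknown example {name!r}; choose from {sorted(_EXAMPLES)}")
    ref = resources.files("xrrmeta.datasets").joinpath(filename)
    with resources.as_file(ref) as fp:
        return read_meta_csv(fp)
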