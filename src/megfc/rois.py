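"""Default-mode-network seed regions.

Twelve ROIs spanning the DMN (angular gyri, posterior cingulate/precuneus,
medial prefrontal, inferior temporal, anterior cingulate; 6-mm-radius
spheres in MNI space), split into an anterior and a posterior partition.
The packaged table ships with the package and is the default seed set.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import SchemaError

ROI_NAMES = (
    "LAG", "RAG", "LPCC", "RPCC", "LvMPFC", "RvMPFC",
    "LdMPFC", "RdMPFC", "LITG", "RITG", "LACC", "RACC",
)

ANTERIOR = frozenset({"LvMPFC", "RvMPFC", "LdMPFC", "RdMPFC", "LACC", "RACC"})
POSTERIOR = frozenset({"LAG", "RAG", "LPCC", "RPCC", "LITG", "RITG"})

DEFAULT_ROI_RADIUS_MM = 6.0

_REQUIRED_COLS = ("name", "x_mni", "y_mni", "z_mni", "partition")


@dataclass(frozen=True)
class ROITable:
    """Validated seed-region table.

    ``coords_mni`` rows follow the order of ``names``; ``partition`` maps
    each name to ``"anterior"`` or ``"posterior"``.
    """

    names: tuple
    coords_mni: np.ndarray          # (n_roi, 3), mm
    partition: dict
    radius_mm: float = DEFAULT_ROI_RADIUS_MM

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def coord(self, name: str) -> np.ndarray:
        return self.coords_mni[self.index(name)]

    @property
    def pairs(self):
        """All unordered ROI-name pairs, lexicographic in table order."""
        out = []
        for i in range(len(self.names)):
            for j in range(i + 1, len(self.names)):
                out.append((self.names[i], self.names[j]))
        return out


def load_roi_table(source=None) -> ROITable:
    """Load and validate a seed table (TSV: name, x_mni, y_mni, z_mni, partition).

    With no argument the packaged 12-ROI DMN table is returned.
    """
    if source is None:
        with resources.files("megfc.data").joinpath("dmn_rois.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t")

    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"ROI table missing column(s): {missing}")
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise SchemaError(f"duplicate ROI names: {dupes}")
    coords = df[["x_mni", "y_mni", "z_mni"]].to_numpy()
    try:
        coords = coords.astype(float)
    except (TypeError, ValueError) as exc:
        for i, row in enumerate(df[["x_mni", "y_mni", "z_mni"]].itertuples(index=False)):
            try:
                [float(v) for v in row]
            except (TypeError, ValueError):
                raise SchemaError(f"non-numeric coordinate in row {i}") from exc
        raise SchemaError("non-numeric coordinate") from exc
    bad_part = ~df["partition"].isin(["anterior", "posterior"])
    if bad_part.any():
        raise SchemaError(
            f"invalid partition label(s) in rows {np.nonzero(bad_part.to_numpy())[0].tolist()}"
        )
    return ROITable(
        names=tuple(df["name"]),
        coords_mni=coords,
        partition=dict(zip(df["name"], df["partition"])),
    )
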