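"""Region-of-interest atlas for whole-brain PET covariance networks.

The default atlas has 72 nodes: bilateral hippocampus and amygdala (FreeSurfer
subcortical segmentation) followed by the 34 Desikan-Killiany cortical regions
of the left hemisphere and then the right, using FreeSurfer ``aparc`` names
with ``lh-``/``rh-`` prefixes. Exactly 68 regions are flagged cortical; the
cortical subset is the domain on which gene-expression tables are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import ParseError, SchemaError, ValidationError

#: Desikan-Killiany cortical parcels in FreeSurfer ``aparc`` order.
DESIKAN_KILLIANY_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

SUBCORTICAL_REGIONS: tuple[str, ...] = (
    "left-hippocampus",
    "left-amygdala",
    "right-hippocampus",
    "right-amygdala",
)


def _hemisphere_of(name: str) -> str:
    if name.startswith(("lh-", "left-")):
        return "left"
    if name.startswith(("rh-", "right-")):
        return "right"
    return "unknown"


@dataclass(frozen=True)
class RoiAtlas:
    """Ordered ROI naming scheme with cortical flags and hemispheres."""

    names: tuple[str, ...]
    is_cortical: tuple[bool, ...]
    hemisphere: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValidationError("atlas ROI names must be unique")
        if len(self.is_cortical) != len(self.names):
            raise ValidationError("is_cortical must match names in length")
        if not self.hemisphere:
            object.__setattr__(
                self, "hemisphere", tuple(_hemisphere_of(n) for n in self.names)
            )
        elif len(self.hemisphere) != len(self.names):
            raise ValidationError("hemisphere must match names in length")

    @property
    def n_rois(self) -> int:
        return len(self.names)

    @property
    def cortical_names(self) -> tuple[str, ...]:
        return tuple(n for n, c in zip(self.names, self.is_cortical) if c)

    @property
    def subcortical_names(self) -> tuple[str, ...]:
        return tuple(n for n, c in zip(self.names, self.is_cortical) if not c)

    def index_of(self, names) -> list[int]:
        lookup = {n: i for i, n in enumerate(self.names)}
        try:
            return [lookup[n] for n in names]
        except KeyError as exc:
            raise SchemaError(f"ROI {exc.args[0]!r} not in atlas") from None

    @classmethod
    def from_file(cls, path: str | Path) -> "RoiAtlas":
        """Read a two-column delimited file ``name, is_cortical``."""
        path = Path(path)
        sep = "\t" if path.suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        for col in ("name", "is_cortical"):
            if col not in df.columns:
                raise SchemaError(f"atlas file missing column {col!r}")
        flags = []
        for i, raw in enumerate(df["is_cortical"]):
            if isinstance(raw, str):
                token = raw.strip().lower()
                if token in {"true", "1", "yes"}:
                    flags.append(True)
                elif token in {"false", "0", "no"}:
                    flags.append(False)
                else:
                    raise ParseError(f"row {i}: cannot parse is_cortical {raw!r}")
            else:
                flags.append(bool(raw))
        return cls(tuple(df["name"].astype(str)), tuple(flags))


def default_atlas() -> RoiAtlas:
    """The 72-ROI atlas: 4 subcortical nodes then 34 left + 34 right DK parcels."""
    names = list(SUBCORTICAL_REGIONS)
    names += [f"lh-{r}" for r in DESIKAN_KILLIANY_REGIONS]
    names += [f"rh-{r}" for r in DESIKAN_KILLIANY_REGIONS]
    is_cortical = [False] * 4 + [True] * 68
    return RoiAtlas(tuple(names), tuple(is_cortical))
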