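"""Parcellation tables: ordered region lists with hemisphere and lobe labels.

The parcellation fixes the node order of every connectome in an analysis.
All subjects and modalities must share one :class:`ParcellationSpec`; edge
vectorization (see :mod:`plscog.connectome`) inherits its ordering from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: Anatomical groupings used for reporting, in display order.
LOBES = ("frontal", "parietal", "occipital", "subcortical", "temporal")

HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class ParcellationSpec:
    """An ordered table of brain regions.

    Parameters
    ----------
    regions : pandas.DataFrame
        Columns ``label`` (unique str), ``hemisphere`` (``left``/``right``)
        and ``lobe`` (one of :data:`LOBES`). Row order is the node order of
        every connectivity matrix built against this parcellation.
    """

    regions: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"label", "hemisphere", "lobe"}
        missing = required - set(self.regions.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        labels = self.regions["label"]
        if labels.duplicated().any():
            dupes = labels[labels.duplicated()].tolist()
            raise ValueError(f"duplicate region labels: {dupes}")
        bad_hemi = set(self.regions["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        bad_lobe = set(self.regions["lobe"]) - set(LOBES)
        if bad_lobe:
            raise ValueError(f"unknown lobe labels: {sorted(bad_lobe)}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def labels(self) -> list[str]:
        return self.regions["label"].tolist()

    @property
    def lobes(self) -> list[str]:
        """Lobe label per region, in node order."""
        return self.regions["lobe"].tolist()

    def lobe_of(self, region: int | str) -> str:
        """Lobe of a region given by index (0-based) or label."""
        if isinstance(region, str):
            match = self.regions.index[self.regions["label"] == region]
            if len(match) == 0:
                raise KeyError(f"unknown region label {region!r}")
            return self.regions.loc[match[0], "lobe"]
        if not 0 <= region < self.n_regions:
            raise IndexError(
                f"region index {region} out of range for {self.n_regions} regions"
            )
        return self.regions.iloc[region]["lobe"]

    @classmethod
    def from_tsv(cls, path) -> "ParcellationSpec":
        """Read a 3-column TSV (label, hemisphere, lobe) with a header row."""
        table = pd.read_csv(path, sep="\t", dtype=str)
        return cls(table.reset_index(drop=True))

    @classmethod
    def desikan_killiany_82(cls) -> "ParcellationSpec":
        """The packaged 82-region Desikan-Killiany parcellation.

        34 cortical plus 7 subcortical regions per hemisphere, grouped into
        frontal, parietal, occipital, subcortical and temporal divisions
        (the insula is grouped with the subcortical division for reporting).
        """
        ref = resources.files("plscog.data").joinpath("dk82.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)
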