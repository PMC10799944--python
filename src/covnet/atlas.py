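"""Cortical parcellation atlases.

The package's networks are built over a fixed, ordered list of cortical
regions.  The default is the Desikan–Killiany parcellation: 34 gyral-based
regions per hemisphere, 68 in total, the standard FreeSurfer ``aparc``
scheme.  Region labels follow the ``lh.<name>`` / ``rh.<name>`` convention;
``lh_<name>`` (the aparcstats2table dialect) is accepted on input and
normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RegionalAtlas", "desikan_atlas", "synthetic_atlas", "normalize_label"]

# FreeSurfer aparc (Desikan–Killiany) region names, standard output order.
DESIKAN_REGIONS: tuple[str, ...] = (
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


def normalize_label(label: str) -> str:
    """Canonicalize a region label: lowercase, ``lh_x``/``lh-x`` -> ``lh.x``."""
    lab = label.strip().lower()
    for hemi in ("lh", "rh"):
        for sep in ("_", "-"):
            prefix = hemi + sep
            if lab.startswith(prefix):
                return hemi + "." + lab[len(prefix):]
    return lab


@dataclass(frozen=True)
class RegionalAtlas:
    """An ordered, immutable list of region labels with hemisphere tags.

    The ordering is fixed for a run: every morphometry table, association
    matrix and nodal-metric vector is aligned to it.
    """

    region_ids: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.hemispheres):
            raise ValueError("region_ids and hemispheres must have equal length")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("atlas region labels must be unique")
        bad = set(self.hemispheres) - {"lh", "rh", "na"}
        if bad:
            raise ValueError(f"unknown hemisphere tags: {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index(self, label: str) -> int:
        """Position of ``label`` (after normalization) in the atlas order."""
        norm = normalize_label(label)
        try:
            return self._lookup[norm]
        except KeyError:
            raise KeyError(f"region {label!r} is not in the atlas") from None

    @property
    def _lookup(self) -> dict[str, int]:
        # frozen dataclass: cache on the instance dict via object.__setattr__
        cached = self.__dict__.get("_lookup_cache")
        if cached is None:
            cached = {normalize_label(r): i for i, r in enumerate(self.region_ids)}
            object.__setattr__(self, "_lookup_cache", cached)
        return cached


def desikan_atlas() -> RegionalAtlas:
    """The 68-region Desikan–Killiany atlas (34 per hemisphere, lh then rh)."""
    labels = tuple(f"{h}.{r}" for h in ("lh", "rh") for r in DESIKAN_REGIONS)
    hemis = tuple(h for h in ("lh", "rh") for _ in DESIKAN_REGIONS)
    return RegionalAtlas(labels, hemis)


def synthetic_atlas(n_regions: int) -> RegionalAtlas:
    """A generic atlas of ``n_regions`` labelled placeholder parcels.

    Used by simulations that deviate from the 68-region default (e.g. very
    small test fixtures).  Regions are split evenly between hemispheres.
    """
    if n_regions == 68:
        return desikan_atlas()
    half = n_regions // 2
    labels = []
    hemis = []
    for i in range(n_regions):
        hemi = "lh" if i < half else "rh"
        labels.append(f"{hemi}.region{i:03d}")
        hemis.append(hemi)
    return RegionalAtlas(tuple(labels), tuple(hemis))
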