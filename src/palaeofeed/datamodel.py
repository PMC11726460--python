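"""Core record types for a multi-proxy cattle palaeodiet dataset.

The dataset joins three carbon-isotope proxies for cattle diet — bone-collagen
delta13C, pottery dairy-lipid delta13C (C16:0 fatty acid) and sequential
tooth-enamel bioapatite delta13C — with sequential dentine amino-acid
delta15N and per-site environmental covariates (reconstructed percent forest
cover, palaeoclimate, hydrology).  Records are plain dataclasses; tabular I/O
lives in :mod:`palaeofeed.isotope_io`.

Conventions
-----------
* delta values are per-mil: delta13C/delta18O vs VPDB, delta15N vs AIR.
* Intra-tooth sample positions are millimetres from the enamel-root junction
  (ERJ), increasing toward the occlusal surface.  Hypsodont molar crowns
  mineralize occlusal-to-cervical, so the *earliest formed* enamel has the
  *largest* position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TISSUES",
    "TAXA",
    "CULTURES",
    "Site",
    "BulkSample",
    "EnamelIncrement",
    "DentineIncrement",
    "ToothSeries",
    "Dataset",
]

TISSUES = ("collagen", "dairy_c16", "bioapatite")
TAXA = ("cattle", "deer", "ruminant_dairy")
CULTURES = ("LBK", "ALP")

#: sanity window for site coordinates (decimal degrees), central Europe
LON_BOUNDS = (-15.0, 40.0)
LAT_BOUNDS = (35.0, 60.0)

#: sanity bound for any delta13C in a C3 terrestrial food web (per-mil VPDB)
D13C_BOUNDS = (-45.0, 0.0)


@dataclass
class Site:
    """A settlement site: the spatial and correlation unit of the dataset.

    Environmental fields may be ``None`` until enrichment (e.g. ``mfc`` is
    sampled from forest-cover reconstructions by the spatial stage).
    """

    site_id: str
    name: str = ""
    longitude: float = float("nan")
    latitude: float = float("nan")
    mfc: float | None = None            # mean forest cover, percent [0, 100]
    pmw: float | None = None            # mean winter precipitation, mm
    pms: float | None = None            # mean summer precipitation, mm
    tmw: float | None = None            # mean winter temperature, deg C
    tms: float | None = None            # mean summer temperature, deg C
    river_distance: float | None = None  # km to nearest river
    strahler: int | None = None         # Strahler stream order >= 1
    drainage: str | None = None         # basin label
    culture: str | None = None          # LBK | ALP
    extra: dict = field(default_factory=dict)

    def problems(self) -> list[str]:
        out = []
        if not self.site_id:
            out.append("site_id empty")
        if not (LON_BOUNDS[0] <= self.longitude <= LON_BOUNDS[1]):
            out.append(f"longitude {self.longitude} outside {LON_BOUNDS}")
        if not (LAT_BOUNDS[0] <= self.latitude <= LAT_BOUNDS[1]):
            out.append(f"latitude {self.latitude} outside {LAT_BOUNDS}")
        if self.mfc is not None and not (0.0 <= self.mfc <= 100.0):
            out.append(f"mfc {self.mfc} outside [0, 100]")
        if self.strahler is not None and self.strahler < 1:
            out.append(f"strahler {self.strahler} < 1")
        if self.culture is not None and self.culture not in CULTURES:
            out.append(f"culture {self.culture!r} not in {CULTURES}")
        return out


@dataclass
class BulkSample:
    """One bulk delta13C record: collagen, dairy C16:0 lipid or bioapatite.

    ``d13c_c18`` is the C18:0 fatty-acid value of a dairy extract, needed for
    the dairy-origin test (delta13C_18:0 - delta13C_16:0 <= -3.1 per-mil);
    it is optional because some extracts lack a usable C18:0 measurement.
    """

    sample_id: str
    site_id: str
    tissue: str
    taxon: str
    d13c: float
    d13c_c18: float | None = None

    def problems(self) -> list[str]:
        out = []
        if self.tissue not in TISSUES:
            out.append(f"tissue {self.tissue!r} not in {TISSUES}")
        if self.taxon not in TAXA:
            out.append(f"taxon {self.taxon!r} not in {TAXA}")
        if not (D13C_BOUNDS[0] <= self.d13c <= D13C_BOUNDS[1]):
            out.append(f"d13c {self.d13c} outside {D13C_BOUNDS}")
        if self.tissue == "dairy_c16" and self.taxon != "ruminant_dairy":
            out.append("tissue dairy_c16 requires taxon ruminant_dairy")
        if self.d13c_c18 is not None and not (
            D13C_BOUNDS[0] <= self.d13c_c18 <= D13C_BOUNDS[1]
        ):
            out.append(f"d13c_c18 {self.d13c_c18} outside {D13C_BOUNDS}")
        return out


@dataclass
class EnamelIncrement:
    """A drilled enamel bioapatite sample at one crown position."""

    tooth_id: str
    position_erj: float  # mm from ERJ toward the occlusal surface
    d13c_bioap: float
    d18o_bioap: float


@dataclass
class DentineIncrement:
    """Sequential dentine CSIA delta15N of glutamate (Glx) and phenylalanine."""

    tooth_id: str
    position_erj: float
    d15n_glx: float
    d15n_phe: float


@dataclass
class ToothSeries:
    """One cattle third molar: ordered enamel and dentine increment series.

    Increments are stored occlusal-first (descending ``position_erj``), i.e.
    in order of formation.
    """

    tooth_id: str
    site_id: str
    crown_height: float  # mm
    enamel: list[EnamelIncrement] = field(default_factory=list)
    dentine: list[DentineIncrement] = field(default_factory=list)

    def problems(self) -> list[str]:
        out = []
        if self.crown_height <= 0:
            out.append(f"crown_height {self.crown_height} <= 0")
        for inc in list(self.enamel) + list(self.dentine):
            if not (0.0 <= inc.position_erj <= self.crown_height):
                out.append(
                    f"{type(inc).__name__} position {inc.position_erj} outside "
                    f"[0, crown_height={self.crown_height}]"
                )
        for series in (self.enamel, self.dentine):
            pos = [i.position_erj for i in series]
            if any(a <= b for a, b in zip(pos, pos[1:])):
                out.append("increments not strictly descending in position_erj")
        return out


@dataclass
class Dataset:
    """All records of one study, keyed collections with referential integrity."""

    sites: dict[str, Site] = field(default_factory=dict)
    bulk: list[BulkSample] = field(default_factory=list)
    teeth: list[ToothSeries] = field(default_factory=list)

    def bulk_by_tissue(self, tissue: str, taxon: str | None = None) -> list[BulkSample]:
        return [
            s
            for s in self.bulk
            if s.tissue == tissue and (taxon is None or s.taxon == taxon)
        ]
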