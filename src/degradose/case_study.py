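"""The shipped vessel-closure case study.

A biodegradable vessel closure system: a 100 mg 75:25 poly(glycolide-lactide)
suture, 30 mg of a 50:25:25 glycolide-caprolactone-trimethylene carbonate
copolymer (anchor and cap seals), and 5 mg of a polyethylene glycol sealant,
with a scaling factor of 2 for bilateral use. The hazard database carries
oral-NOAEL points of departure and per-window modifying factors for the five
terminal hydrolysis products; the single mass-loss curve is a synthetic
reconstruction of the published first-week in vivo observation (2% loss in
7 days) for the glycolide-containing material.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .composition import DeviceBOM, PolymerSpec
from .exposure import MassLossCurve
from .hazard import HazardDatabase
from .io import load_bom, load_curves_dir, load_hazard_db, load_polymer_registry

CAS_ETHYLENE_GLYCOL = "107-21-1"
CAS_LACTIC_ACID = "50-21-5"
CAS_GLYCOLIC_ACID = "79-14-1"
CAS_CAPROLACTONE = "502-44-3"
CAS_TMC = "2453-03-4"


def data_dir() -> Path:
    """Directory holding the packaged case-study input documents."""
    return Path(resources.files("degradose") / "data" / "case_study")


def load_case_study() -> tuple[
    DeviceBOM, dict[str, PolymerSpec], HazardDatabase, dict[str, list[MassLossCurve]]
]:
    """Load the full case study: BOM, polymer registry, hazard DB, curves."""
    d = data_dir()
    registry = load_polymer_registry(d / "polymers.yaml")
    bom = load_bom(d / "bom.yaml", registry)
    hazards = load_hazard_db(d / "hazards.yaml")
    curves = load_curves_dir(d)
    return bom, registry, hazards, curves
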