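"""Readers and writers for the structured input documents.

Three YAML documents describe an assessment — a polymer registry (monomers +
polymers), a device bill of materials, and a hazard database — plus optional
per-constituent mass-loss curves as 2-column CSV files (``t_days,
fraction_lost``) with ``# provenance:`` / ``# label:`` comment headers.
Curve files are matched to constituents by filename prefix up to the first
underscore (the CAS RN). All machine-readable output is comma-separated,
UTF-8, '.' decimal separator; thousands separators appear only in rendered
reports.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pydantic
import yaml

from .composition import BOMEntry, DeviceBOM, Monomer, PolymerComponent, PolymerSpec
from .errors import InputError
from .exposure import SCENARIOS, CurveProvenance, MassLossCurve
from .hazard import HazardDatabase, HazardRecord, PODRecord, StudyDurationClass, UFSet

BASE_UF = 10.0  # conventional interindividual and interspecies factors


def _load_yaml(path: str | Path) -> dict:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise InputError(f"malformed YAML: {exc}", path=str(path)) from exc
    if not isinstance(doc, dict):
        raise InputError("document root must be a mapping", path=str(path))
    return doc


def _first_error_field(exc: pydantic.ValidationError) -> str:
    errs = exc.errors()
    return ".".join(str(p) for p in errs[0]["loc"]) if errs else ""


def load_polymer_registry(path: str | Path) -> dict[str, PolymerSpec]:
    """Load monomer and polymer definitions; returns polymers keyed by name."""
    doc = _load_yaml(path)
    monomers: dict[str, Monomer] = {}
    for rec in doc.get("monomers", []):
        try:
            m = Monomer(**rec)
        except pydantic.ValidationError as exc:
            raise InputError(
                f"invalid monomer: {exc.errors()[0]['msg']}",
                path=str(path), record=rec.get("name", "?"),
                field=_first_error_field(exc),
            ) from exc
        if m.name in monomers:
            raise InputError("duplicate monomer name", path=str(path), record=m.name)
        monomers[m.name] = m
    polymers: dict[str, PolymerSpec] = {}
    for rec in doc.get("polymers", []):
        name = rec.get("name", "?")
        components = []
        for comp in rec.get("components", []):
            mono_name = comp.get("monomer")
            if mono_name not in monomers:
                raise InputError(
                    f"unknown monomer {mono_name!r}", path=str(path),
                    record=name, field="components.monomer",
                )
            components.append(
                PolymerComponent(monomer=monomers[mono_name], ratio=comp.get("ratio"))
            )
        try:
            spec = PolymerSpec(
                name=name,
                components=components,
                ratio_basis=rec.get("ratio_basis", "mass"),
                cas_rn=rec.get("cas_rn"),
            )
        except pydantic.ValidationError as exc:
            raise InputError(
                f"invalid polymer: {exc.errors()[0]['msg']}",
                path=str(path), record=name, field=_first_error_field(exc),
            ) from exc
        if name in polymers:
            raise InputError("duplicate polymer name", path=str(path), record=name)
        polymers[name] = spec
    if not polymers:
        raise InputError("registry defines no polymers", path=str(path))
    return polymers


def load_bom(path: str | Path, registry: dict[str, PolymerSpec]) -> DeviceBOM:
    """Load a device bill of materials, resolving polymers by registry name."""
    doc = _load_yaml(path)
    entries = []
    for i, rec in enumerate(doc.get("entries", [])):
        pname = rec.get("polymer")
        if pname not in registry:
            raise InputError(
                f"unknown polymer {pname!r}", path=str(path), record=i, field="polymer"
            )
        try:
            entries.append(BOMEntry(polymer=registry[pname], mass_mg=rec.get("mass_mg")))
        except pydantic.ValidationError as exc:
            raise InputError(
                f"invalid BOM entry: {exc.errors()[0]['msg']}",
                path=str(path), record=i, field=_first_error_field(exc),
            ) from exc
    if not entries:
        raise InputError("bill of materials has no entries", path=str(path))
    try:
        return DeviceBOM(
            device_name=doc.get("device_name", "unnamed device"),
            entries=entries,
            scaling_factor=doc.get("scaling_factor", 1),
        )
    except pydantic.ValidationError as exc:
        raise InputError(
            f"invalid BOM: {exc.errors()[0]['msg']}",
            path=str(path), field=_first_error_field(exc),
        ) from exc


def load_hazard_db(path: str | Path) -> HazardDatabase:
    """Load the hazard database.

    Each record carries a POD and per-window modifying factors; factors
    beyond the two conventional 10s are stored as a combined
    duration/quality residual (MF / 100).
    """
    doc = _load_yaml(path)
    records: dict[str, HazardRecord] = {}
    for rec in doc.get("records", []):
        cas = rec.get("constituent_cas", "?")
        if cas in records:
            raise InputError("duplicate constituent CAS", path=str(path), record=cas)
        try:
            pod = PODRecord(
                constituent_cas=cas,
                constituent_name=rec.get("constituent_name", ""),
                pod_mg_per_kg_day=rec.get("pod_mg_per_kg_day"),
                study_duration_class=rec.get("study_duration_class"),
                endpoint_note=rec.get("endpoint_note", ""),
                surrogate_of=rec.get("surrogate_of"),
                citation=rec.get("citation", ""),
            )
        except pydantic.ValidationError as exc:
            raise InputError(
                f"invalid hazard record: {exc.errors()[0]['msg']}",
                path=str(path), record=cas, field=_first_error_field(exc),
            ) from exc
        mf_map = rec.get("mf", {})
        ufs = {}
        for s in SCENARIOS:
            if s.value not in mf_map:
                raise InputError(
                    f"missing modifying factor for scenario {s.value!r}",
                    path=str(path), record=cas, field=f"mf.{s.value}",
                )
            mf = float(mf_map[s.value])
            residual = mf / (BASE_UF * BASE_UF)
            if residual < 1.0:
                raise InputError(
                    f"modifying factor {mf:g} below the conventional base of 100",
                    path=str(path), record=cas, field=f"mf.{s.value}",
                )
            ufs[s] = UFSet(
                uf_interindividual=BASE_UF,
                uf_interspecies=BASE_UF,
                uf_duration=residual,
                uf_quality_applicability=1.0,
            )
        records[cas] = HazardRecord(pod=pod, ufs_by_scenario=ufs)
    if not records:
        raise InputError("hazard database has no records", path=str(path))
    return HazardDatabase(records=records)


def load_curve_csv(path: str | Path) -> MassLossCurve:
    """Read a mass-loss curve from a 2-column CSV with comment headers."""
    path = Path(path)
    provenance = CurveProvenance.synthetic
    label = path.stem
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "provenance":
                try:
                    provenance = CurveProvenance(val.strip())
                except ValueError:
                    raise InputError(
                        f"unknown provenance {val.strip()!r}", path=str(path),
                        field="provenance",
                    ) from None
            elif key.strip() == "label":
                label = val.strip()
    df = pd.read_csv(path, comment="#")
    expected = {"t_days", "fraction_lost"}
    if set(df.columns) != expected:
        raise InputError(
            f"curve columns {list(df.columns)} != ['t_days', 'fraction_lost']",
            path=str(path),
        )
    try:
        return MassLossCurve(
            samples=list(zip(df["t_days"].tolist(), df["fraction_lost"].tolist())),
            provenance=provenance,
            label=label,
        )
    except pydantic.ValidationError as exc:
        # surface the offending row index from the validator message
        raise InputError(
            f"invalid curve: {exc.errors()[0]['msg']}", path=str(path)
        ) from exc


def load_curves_dir(directory: str | Path) -> dict[str, list[MassLossCurve]]:
    """Load every ``*.csv`` curve in a directory, keyed by the CAS RN prefix
    of the filename (up to the first underscore)."""
    directory = Path(directory)
    curves: dict[str, list[MassLossCurve]] = {}
    for path in sorted(directory.glob("*.csv")):
        cas = path.stem.split("_", 1)[0]
        curves.setdefault(cas, []).append(load_curve_csv(path))
    return curves


def load_inputs(
    bom_path: str | Path,
    registry_path: str | Path,
    hazard_path: str | Path,
    curves_dir: str | Path | None = None,
) -> tuple[DeviceBOM, dict[str, PolymerSpec], HazardDatabase, dict[str, list[MassLossCurve]]]:
    """Load and validate every assessment input in one call."""
    registry = load_polymer_registry(registry_path)
    bom = load_bom(bom_path, registry)
    hazards = load_hazard_db(hazard_path)
    curves = load_curves_dir(curves_dir) if curves_dir is not None else {}
    return bom, registry, hazards, curves


# --- writers (round-trip counterparts) ---------------------------------------


def dump_polymer_registry(polymers: dict[str, PolymerSpec], path: str | Path) -> None:
    monomers: dict[str, Monomer] = {}
    for spec in polymers.values():
        for comp in spec.components:
            monomers.setdefault(comp.monomer.name, comp.monomer)
    doc = {
        "monomers": [
            m.model_dump(exclude_none=True, exclude_defaults=False)
            for m in monomers.values()
        ],
        "polymers": [
            {
                "name": spec.name,
                **({"cas_rn": spec.cas_rn} if spec.cas_rn else {}),
                "ratio_basis": spec.ratio_basis.value,
                "components": [
                    {"monomer": c.monomer.name, "ratio": c.ratio}
                    for c in spec.components
                ],
            }
            for spec in polymers.values()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


def dump_bom(bom: DeviceBOM, path: str | Path) -> None:
    doc = {
        "device_name": bom.device_name,
        "scaling_factor": bom.scaling_factor,
        "entries": [
            {"polymer": e.polymer.name, "mass_mg": e.mass_mg} for e in bom.entries
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


def dump_hazard_db(db: HazardDatabase, path: str | Path) -> None:
    from .hazard import modifying_factor

    doc = {"records": []}
    for cas, rec in db.records.items():
        entry = {
            "constituent_cas": cas,
            "constituent_name": rec.pod.constituent_name,
            "pod_mg_per_kg_day": rec.pod.pod_mg_per_kg_day,
            "study_duration_class": rec.pod.study_duration_class.value,
            "endpoint_note": rec.pod.endpoint_note,
            "citation": rec.pod.citation,
            "mf": {
                s.value: modifying_factor(rec.ufs_by_scenario[s]) for s in SCENARIOS
            },
        }
        if rec.pod.surrogate_of:
            entry["surrogate_of"] = rec.pod.surrogate_of
        doc["records"].append(entry)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


def write_curve_csv(curve: MassLossCurve, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# provenance: {curve.provenance.value}\n")
        if curve.label:
            fh.write(f"# label: {curve.label}\n")
        fh.write("t_days,fraction_lost\n")
        for t, f in curve.samples:
            fh.write(f"{t!r},{f!r}\n")
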