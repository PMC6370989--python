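"""Machine-geometry profiles (structured YAML -> :class:`MachineProfile`).

A profile bundles the leaf table, collimator distances and materials.
The shipped default, ``clinac2300ix-6mv``, uses public vendor-style
values for a Millennium-120 bank on a 6 MV machine; every number is
editable because none of them is tied to a specific installation.

Schema (all lengths mm, densities g/cm^3)::

    name: <profile name>
    sad_mm: 1000.0
    mlc:
      source_to_mlc_mm: 509.0
      physical_height_mm: 67.0
      tip: {radius_mm, central_angle_deg, flat_length_mm,
            side_arc_radius_mm, side_arc_angle_deg}
      interleaf: {band_width_mm, path_fraction}
      widths_mm: [10.0 x10, 5.0 x40, 10.0 x10]   # optional, default pattern
      material: {name, density, composition: {element: mass fraction}}
    jaws:
      x: {z_mm, thickness_mm}
      y: {z_mm, thickness_mm}
      material: {...}
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .mlc import (LeafSpec, MachineConfigError, MachineProfile, MLCBank,
                  default_leaf_pairs)
from .xsec import Material

DEFAULT_PROFILE = "clinac2300ix-6mv"


def _material_from(cfg: dict) -> Material:
    return Material.normalized(cfg["name"], float(cfg["density"]),
                               {k: float(v) for k, v in cfg["composition"].items()})


def load_machine_profile(source: str | Path | None = None) -> MachineProfile:
    """Load a machine profile by name (bundled) or from a YAML file path."""
    if source is None:
        source = DEFAULT_PROFILE
    p = Path(str(source))
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text()
    else:
        ref = resources.files("mlcdose.data") / f"{source}.yaml"
        if not ref.is_file():
            raise MachineConfigError(f"unknown machine profile {source!r}")
        text = ref.read_text()
    cfg = yaml.safe_load(text)
    try:
        mlc_cfg = cfg["mlc"]
        tip = mlc_cfg["tip"]
        mat = _material_from(mlc_cfg["material"])
        jaw_mat = _material_from(cfg["jaws"]["material"])
        pairs = default_leaf_pairs(
            physical_height=float(mlc_cfg["physical_height_mm"]),
            tip_radius=float(tip["radius_mm"]),
            tip_central_angle_deg=float(tip["central_angle_deg"]),
            tip_flat_length=float(tip["flat_length_mm"]),
            tip_side_arc_radius=float(tip["side_arc_radius_mm"]),
            tip_side_arc_angle_deg=float(tip["side_arc_angle_deg"]),
            density=mat.density,
            material=mat.name,
        )
        if "widths_mm" in mlc_cfg:
            widths = [float(w) for w in mlc_cfg["widths_mm"]]
            if len(widths) != len(pairs):
                raise MachineConfigError("widths_mm must list 60 values")
            pairs = [LeafSpec(**{**vars(s), "width_at_iso": w})
                     for s, w in zip(pairs, widths)]
        il = mlc_cfg.get("interleaf", {})
        bank = MLCBank(
            pairs=pairs,
            source_to_mlc_distance=float(mlc_cfg["source_to_mlc_mm"]),
            sad=float(cfg["sad_mm"]),
            interleaf_band_width=float(il.get("band_width_mm", 0.3)),
            interleaf_path_fraction=float(il.get("path_fraction", 0.78)),
        )
        return MachineProfile(
            name=cfg["name"],
            bank=bank,
            mlc_material=mat,
            jaw_material=jaw_mat,
            x_jaw_z=float(cfg["jaws"]["x"]["z_mm"]),
            x_jaw_thickness=float(cfg["jaws"]["x"]["thickness_mm"]),
            y_jaw_z=float(cfg["jaws"]["y"]["z_mm"]),
            y_jaw_thickness=float(cfg["jaws"]["y"]["thickness_mm"]),
        )
    except KeyError as exc:
        raise MachineConfigError(f"machine profile missing key: {exc}") from exc
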