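"""Tunable geometric thresholds for interaction detection.

Every distance (Angstrom) and angle (degrees) used by the detectors is a
named parameter with a default and an allowed range; user overrides outside
the range are rejected with the range printed. Boolean switches control the
convention choices that real structures leave open (histidine charge,
hydrogen mode, heavy-atom-only cutoffs).
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Threshold:
    default: float
    min: float
    max: float
    unit: str  # "A" | "deg"
    doc: str = ""


# name -> Threshold(default, min, max)
THRESHOLDS: dict[str, Threshold] = {
    "residue_cutoff":   Threshold(5.0, 2.0, 10.0, "A",
                                  "inter-residue contact cutoff"),
    # hydrogen bonds
    "hbond.da_max":     Threshold(3.5, 2.4, 4.1, "A", "donor...acceptor max"),
    "hbond.ha_max":     Threshold(2.7, 1.5, 3.2, "A", "hydrogen...acceptor max"),
    "hbond.dha_min":    Threshold(120.0, 90.0, 180.0, "deg",
                                  "donor-H...acceptor min angle"),
    "hbond.cda_min":    Threshold(90.0, 60.0, 180.0, "deg",
                                  "heavy-atom mode donor-angle surrogate"),
    # salt bridges
    "salt_bridge.max":  Threshold(4.0, 2.5, 5.0, "A",
                                  "anionic O/N to cationic N max"),
    # weak (C-H) hydrogen bonds
    "weak_hbond.ca_max":    Threshold(3.8, 3.0, 4.5, "A", "carbon...acceptor max"),
    "weak_hbond.ha_max":    Threshold(2.8, 1.8, 3.4, "A"),
    "weak_hbond.cha_min":   Threshold(110.0, 90.0, 180.0, "deg"),
    # bridged contacts
    "water_mediated.max":   Threshold(3.5, 2.5, 4.0, "A",
                                      "water O to polar atom max, each leg"),
    "metal_mediated.tight": Threshold(2.8, 1.8, 3.5, "A",
                                      "coordination max, transition metals/Mg"),
    "metal_mediated.loose": Threshold(3.0, 2.0, 3.8, "A",
                                      "coordination max, Na/K/Ca"),
    # covalent-like
    "disulfide.max":    Threshold(2.5, 1.8, 3.0, "A", "SG-SG max"),
    "halogen.extra":    Threshold(0.2, 0.0, 1.0, "A",
                                  "X...A max = vdW sum + extra"),
    "halogen.cxa_min":  Threshold(140.0, 90.0, 180.0, "deg",
                                  "C-X...A sigma-hole angle min"),
    # pi family
    "pi_pi.max":            Threshold(5.5, 3.0, 7.0, "A", "centroid-centroid max"),
    "pi_pi.planar_max":     Threshold(30.0, 0.0, 60.0, "deg",
                                      "stacked plane-plane angle max"),
    "pi_pi.t_min":          Threshold(60.0, 30.0, 90.0, "deg",
                                      "T-shaped plane-plane angle min"),
    "pi_pi.offset_max":     Threshold(2.5, 0.0, 4.0, "A",
                                      "stacked centroid lateral offset max"),
    "cation_pi.max":        Threshold(6.0, 3.0, 7.0, "A"),
    "cation_pi.axial_max":  Threshold(45.0, 0.0, 90.0, "deg"),
    "anion_pi.max":         Threshold(5.0, 3.0, 6.0, "A"),
    "anion_pi.axial_max":   Threshold(45.0, 0.0, 90.0, "deg"),
    "lone_pair_pi.max":     Threshold(3.7, 2.5, 4.5, "A"),
    "lone_pair_pi.axial_max": Threshold(40.0, 0.0, 90.0, "deg"),
    "amino_pi.max":         Threshold(5.5, 3.0, 6.5, "A"),
    "amino_pi.axial_max":   Threshold(50.0, 0.0, 90.0, "deg"),
    "onsh_pi.h_max":        Threshold(3.5, 2.0, 4.5, "A", "H...centroid max"),
    "onsh_pi.heavy_max":    Threshold(4.0, 2.5, 5.0, "A",
                                      "heavy-atom mode donor...centroid max"),
    "onsh_pi.axial_max":    Threshold(40.0, 0.0, 90.0, "deg"),
    "ch_pi.h_max":          Threshold(3.5, 2.0, 4.5, "A"),
    "ch_pi.heavy_max":      Threshold(4.5, 2.5, 5.5, "A"),
    "ch_pi.axial_max":      Threshold(55.0, 0.0, 90.0, "deg"),
    # vdW / clash
    "vdw.tol":          Threshold(0.5, 0.0, 1.0, "A",
                                  "contact max = vdW sum + tol"),
    "clash.tol":        Threshold(0.0, 0.0, 0.5, "A",
                                  "clash when d < vdW sum - tol"),
    # SASA
    "sasa.probe":       Threshold(1.4, 1.0, 2.0, "A", "solvent probe radius"),
    "sasa.bsa_min":     Threshold(0.1, 0.0, 5.0, "A",
                                  "min buried area (A^2) for interface residue"),
}

SWITCH_DEFAULTS = {
    "hydrogen_mode": "explicit",      # explicit | heavy_atom
    "place_hydrogens": True,          # add missing polar H in explicit mode
    "his_cationic": True,             # histidine imidazole counts as cationic
    "heavy_atoms_only_cutoff": True,  # residue cutoff over heavy atoms
    "salt_bridge_requires_hbond": False,
    "include_waters_in_sasa": False,
    "sasa_points": 960,
    "pie_includes_proximal": False,
}


@dataclass
class GeometryConfig:
    """Resolved threshold values plus convention switches."""

    values: dict[str, float] = field(
        default_factory=lambda: {k: t.default for k, t in THRESHOLDS.items()})
    switches: dict = field(default_factory=lambda: dict(SWITCH_DEFAULTS))

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def residue_cutoff(self) -> float:
        return self.values["residue_cutoff"]

    @property
    def hydrogen_mode(self) -> str:
        return self.switches["hydrogen_mode"]

    def set(self, name: str, value) -> None:
        """Apply one override, enforcing the allowed range."""
        if name in THRESHOLDS:
            t = THRESHOLDS[name]
            value = float(value)
            if not (t.min <= value <= t.max):
                raise ConfigError(
                    f"{name}={value:g} outside allowed range "
                    f"[{t.min:g}, {t.max:g}] {t.unit}")
            self.values[name] = value
        elif name in SWITCH_DEFAULTS:
            cur = SWITCH_DEFAULTS[name]
            if isinstance(cur, bool):
                if isinstance(value, str):
                    value = value.lower() in ("1", "true", "yes", "on")
                self.switches[name] = bool(value)
            elif isinstance(cur, int):
                self.switches[name] = int(value)
            else:
                if name == "hydrogen_mode" and value not in ("explicit",
                                                             "heavy_atom"):
                    raise ConfigError("hydrogen_mode must be 'explicit' or "
                                      "'heavy_atom'")
                self.switches[name] = value
        else:
            raise ConfigError(f"unknown parameter {name!r}; known: "
                              f"{', '.join(sorted(THRESHOLDS))}")

    def with_overrides(self, overrides: dict) -> "GeometryConfig":
        cfg = GeometryConfig(dict(self.values), dict(self.switches))
        for k, v in overrides.items():
            cfg.set(k, v)
        return cfg

    @classmethod
    def from_overrides(cls, overrides: dict | None = None) -> "GeometryConfig":
        return cls().with_overrides(overrides or {})

    @classmethod
    def from_file(cls, path) -> "GeometryConfig":
        """Flat ``key = value`` config file; '#' starts a comment."""
        overrides = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{ln}: expected 'key = value'")
                k, v = (s.strip() for s in line.split("=", 1))
                overrides[k] = v
        return cls.from_overrides(overrides)

    def to_dict(self) -> dict:
        return {"thresholds": dict(self.values), "switches": dict(self.switches)}

    def describe(self) -> str:
        lines = ["# threshold = value   (allowed range) unit  description"]
        for name, t in THRESHOLDS.items():
            lines.append(f"{name} = {self.values[name]:g}   "
                         f"([{t.min:g}, {t.max:g}] {t.unit})  {t.doc}")
        lines.append("")
        for name, default in SWITCH_DEFAULTS.items():
            lines.append(f"{name} = {self.switches[name]}")
        return "\n".join(lines)
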