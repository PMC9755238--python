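"""Label schemes: mapping of parcellation label ids to names and tissue classes.

A :class:`LabelScheme` decouples the analysis from any particular atlas
numbering: the built-in scheme matches the geometric phantom, and a real
neonatal parcellation (e.g. an 87-region Draw-EM segmentation) can be adapted
by supplying a YAML config with the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: valid tissue classes
TISSUE_CLASSES = frozenset(
    {
        "cortical_gm",
        "subcortical_gm",
        "wm",
        "csf",
        "ventricles",
        "background",
        "brainstem",
        "claustrum_left",
        "claustrum_right",
    }
)

#: classes excluded from total brain volume
TBV_EXCLUDED_CLASSES = frozenset({"background", "csf", "ventricles"})

#: classes pooled for the grey-matter average (claustra count as deep GM)
GM_CLASSES = frozenset(
    {"cortical_gm", "subcortical_gm", "claustrum_left", "claustrum_right"}
)

#: structure roles that control analyses refer to by name
ROLES = ("insular_wm", "insular_cortex", "thalamus", "caudate", "lentiform")


@dataclass(frozen=True)
class LabelDef:
    name: str
    tissue_class: str


@dataclass
class LabelScheme:
    """Mapping label_id -> (name, tissue class) plus named structure roles.

    ``roles`` maps a role name (e.g. ``"thalamus"``) to one or more label
    ids so that anatomically split atlas labels (left/right) can be pooled.
    """

    labels: dict[int, LabelDef]
    roles: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lid, ldef in self.labels.items():
            if ldef.tissue_class not in TISSUE_CLASSES:
                raise ValueError(
                    f"label {lid} ({ldef.name}): unknown tissue class "
                    f"{ldef.tissue_class!r}"
                )
        names = [d.name for d in self.labels.values()]
        if len(set(names)) != len(names):
            raise ValueError("label names must be unique")
        for side in ("left", "right"):
            n = sum(
                1 for d in self.labels.values() if d.tissue_class == f"claustrum_{side}"
            )
            if n != 1:
                raise ValueError(f"scheme must define exactly one claustrum_{side} label")
        self.roles = {k: tuple(v) for k, v in self.roles.items()}
        for role, ids in self.roles.items():
            for lid in ids:
                if lid not in self.labels:
                    raise ValueError(f"role {role!r} refers to unknown label {lid}")

    # -- lookups ----------------------------------------------------------
    def ids_of_class(self, tissue_class: str) -> tuple[int, ...]:
        return tuple(
            lid for lid, d in sorted(self.labels.items()) if d.tissue_class == tissue_class
        )

    def claustrum_id(self, side: str) -> int:
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return self.ids_of_class(f"claustrum_{side}")[0]

    def role_ids(self, role: str) -> tuple[int, ...]:
        if role not in self.roles:
            raise KeyError(f"scheme defines no role {role!r}")
        return self.roles[role]

    def tbv_ids(self) -> tuple[int, ...]:
        return tuple(
            lid
            for lid, d in sorted(self.labels.items())
            if d.tissue_class not in TBV_EXCLUDED_CLASSES
        )

    def gm_ids(self) -> tuple[int, ...]:
        return tuple(
            lid for lid, d in sorted(self.labels.items()) if d.tissue_class in GM_CLASSES
        )

    # -- I/O --------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "labels": {
                int(lid): {"name": d.name, "class": d.tissue_class}
                for lid, d in self.labels.items()
            },
            "roles": {k: list(v) for k, v in self.roles.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabelScheme":
        labels = {
            int(lid): LabelDef(name=spec["name"], tissue_class=spec["class"])
            for lid, spec in d["labels"].items()
        }
        roles = {
            k: tuple(v) if isinstance(v, (list, tuple)) else (v,)
            for k, v in d.get("roles", {}).items()
        }
        return cls(labels=labels, roles=roles)

    @classmethod
    def from_yaml(cls, path) -> "LabelScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def phantom_scheme() -> LabelScheme:
    """The label scheme used by the geometric phantom generator."""
    defs = {
        0: LabelDef("background", "background"),
        1: LabelDef("csf", "csf"),
        2: LabelDef("ventricles", "ventricles"),
        3: LabelDef("cortical_gm", "cortical_gm"),
        4: LabelDef("wm", "wm"),
        5: LabelDef("insular_cortex", "cortical_gm"),
        6: LabelDef("insular_wm", "wm"),
        7: LabelDef("claustrum_left", "claustrum_left"),
        8: LabelDef("claustrum_right", "claustrum_right"),
        9: LabelDef("thalamus", "subcortical_gm"),
        10: LabelDef("caudate", "subcortical_gm"),
        11: LabelDef("lentiform", "subcortical_gm"),
        12: LabelDef("brainstem", "brainstem"),
    }
    roles = {
        "insular_wm": (6,),
        "insular_cortex": (5,),
        "thalamus": (9,),
        "caudate": (10,),
        "lentiform": (11,),
    }
    return LabelScheme(labels=defs, roles=roles)
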