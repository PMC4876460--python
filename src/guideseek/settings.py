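"""The full user parameterization of a guide search.

Three working modes are supported: single-guide Cas9, paired D10A nickases
(Cas9n) and dimeric RNA-guided FokI nucleases (RFN).  The two paired modes
differ only in their default spacer range between the two protospacer
regions: 14-17 nt for RFN (the effective dimerisation window) versus
0-1000 nt for Cas9n.

Off-target filtering is parameterised either in *basic* form (total
mismatch/gap caps plus seed-region caps) or in *specific* form (independent
mismatch / insertion / deletion caps for the seed and non-seed regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

from .sequence import PamPattern

MODES = ("cas9", "cas9n", "rfn")
PAIRED_MODES = ("cas9n", "rfn")


class SettingsError(ValueError):
    """Inconsistent or out-of-range search settings."""


@dataclass(frozen=True)
class BasicBudgets:
    """Caps on totals: whole-protospacer and seed-region mismatches/gaps."""

    max_mm_total: int = 3
    max_gap_total: int = 1
    max_mm_seed: int = 1
    max_gap_seed: int = 0


@dataclass(frozen=True)
class RegionBudgets:
    """Per-region caps on mismatches, insertions (gRNA bulges) and deletions (DNA bulges)."""

    max_mm: int = 0
    max_ins: int = 0
    max_del: int = 0


@dataclass(frozen=True)
class SpecificBudgets:
    seed: RegionBudgets = field(default_factory=RegionBudgets)
    nonseed: RegionBudgets = field(default_factory=lambda: RegionBudgets(max_mm=2, max_ins=1, max_del=1))


@dataclass(frozen=True)
class SearchSettings:
    """Everything the search needs: mode, geometry, PAMs and edit budgets."""

    mode: str = "cas9"
    grna_len: int = 20
    seed_len: int = 12
    on_pam: PamPattern = field(default_factory=lambda: PamPattern("NGG"))
    off_pam: PamPattern = field(default_factory=lambda: PamPattern("NRG"))
    filter_form: str = "basic"
    basic: BasicBudgets = field(default_factory=BasicBudgets)
    specific: SpecificBudgets = field(default_factory=SpecificBudgets)
    spacer_min: Optional[int] = None
    spacer_max: Optional[int] = None
    max_bulged_strands: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SettingsError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.grna_len < 1:
            raise SettingsError("grna_len must be positive")
        if not (0 < self.seed_len <= self.grna_len):
            raise SettingsError("seed_len must satisfy 0 < seed_len <= grna_len")
        if self.filter_form not in ("basic", "specific"):
            raise SettingsError(f"filter_form must be 'basic' or 'specific', got {self.filter_form!r}")
        for name, value in (
            ("max_mm_total", self.basic.max_mm_total),
            ("max_gap_total", self.basic.max_gap_total),
            ("max_mm_seed", self.basic.max_mm_seed),
            ("max_gap_seed", self.basic.max_gap_seed),
            ("seed.max_mm", self.specific.seed.max_mm),
            ("seed.max_ins", self.specific.seed.max_ins),
            ("seed.max_del", self.specific.seed.max_del),
            ("nonseed.max_mm", self.specific.nonseed.max_mm),
            ("nonseed.max_ins", self.specific.nonseed.max_ins),
            ("nonseed.max_del", self.specific.nonseed.max_del),
        ):
            if value < 0:
                raise SettingsError(f"budget {name} must be >= 0")
        if self.mode in PAIRED_MODES:
            if self.spacer_min is None or self.spacer_max is None:
                raise SettingsError(f"mode {self.mode!r} requires spacer_min and spacer_max")
            if self.spacer_min < 0:
                raise SettingsError("spacer_min must be >= 0")
            if self.spacer_min > self.spacer_max:
                raise SettingsError("spacer_min must not exceed spacer_max")
        if self.max_bulged_strands not in (0, 1, 2):
            raise SettingsError("max_bulged_strands must be 0, 1 or 2")

    # --- derived caps used to bound the alignment band -----------------
    @property
    def max_ins_total(self) -> int:
        """Upper bound on total insertions (gRNA bulges) any passing site can carry."""
        if self.filter_form == "basic":
            return self.basic.max_gap_total
        return self.specific.seed.max_ins + self.specific.nonseed.max_ins

    @property
    def max_del_total(self) -> int:
        """Upper bound on total deletions (DNA bulges) any passing site can carry."""
        if self.filter_form == "basic":
            return self.basic.max_gap_total
        return self.specific.seed.max_del + self.specific.nonseed.max_del

    @property
    def seed_start(self) -> int:
        """0-based protospacer index where the PAM-proximal seed region begins."""
        return self.grna_len - self.seed_len

    def to_dict(self) -> dict:
        """Serialize with the key names used by the config file / settings echo."""
        d = {
            "mode": self.mode,
            "grna-length": self.grna_len,
            "seed-length": self.seed_len,
            "on-pam": self.on_pam.code,
            "off-pam": self.off_pam.code,
            "filter": self.filter_form,
            "basic": {
                "max-mm-total": self.basic.max_mm_total,
                "max-gap-total": self.basic.max_gap_total,
                "max-mm-seed": self.basic.max_mm_seed,
                "max-gap-seed": self.basic.max_gap_seed,
            },
            "specific": {
                "seed": {
                    "max-mm": self.specific.seed.max_mm,
                    "max-ins": self.specific.seed.max_ins,
                    "max-del": self.specific.seed.max_del,
                },
                "nonseed": {
                    "max-mm": self.specific.nonseed.max_mm,
                    "max-ins": self.specific.nonseed.max_ins,
                    "max-del": self.specific.nonseed.max_del,
                },
            },
            "max-bulged-strands": self.max_bulged_strands,
        }
        if self.spacer_min is not None:
            d["spacer-min"] = self.spacer_min
        if self.spacer_max is not None:
            d["spacer-max"] = self.spacer_max
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SearchSettings":
        base = default_settings(d.get("mode", "cas9"))
        return update_settings(base, d)


def default_settings(mode: str = "cas9") -> SearchSettings:
    """Mode-appropriate defaults: RFN spacer 14-17 nt, Cas9n spacer 0-1000 nt."""
    if mode == "rfn":
        return SearchSettings(mode="rfn", spacer_min=14, spacer_max=17)
    if mode == "cas9n":
        return SearchSettings(mode="cas9n", spacer_min=0, spacer_max=1000)
    if mode == "cas9":
        return SearchSettings(mode="cas9")
    raise SettingsError(f"unknown mode {mode!r}; expected one of {MODES}")


def update_settings(settings: SearchSettings, d: dict) -> SearchSettings:
    """Apply a (possibly partial) config-file dictionary on top of ``settings``."""
    kw: dict = {}
    simple = {
        "mode": "mode",
        "grna-length": "grna_len",
        "seed-length": "seed_len",
        "filter": "filter_form",
        "spacer-min": "spacer_min",
        "spacer-max": "spacer_max",
        "max-bulged-strands": "max_bulged_strands",
    }
    for key, attr in simple.items():
        if key in d and d[key] is not None:
            kw[attr] = d[key]
    if d.get("on-pam"):
        kw["on_pam"] = PamPattern(d["on-pam"])
    if d.get("off-pam"):
        kw["off_pam"] = PamPattern(d["off-pam"])
    if "basic" in d and d["basic"]:
        b = d["basic"]
        kw["basic"] = BasicBudgets(
            max_mm_total=b.get("max-mm-total", settings.basic.max_mm_total),
            max_gap_total=b.get("max-gap-total", settings.basic.max_gap_total),
            max_mm_seed=b.get("max-mm-seed", settings.basic.max_mm_seed),
            max_gap_seed=b.get("max-gap-seed", settings.basic.max_gap_seed),
        )
    if "specific" in d and d["specific"]:
        sp = d["specific"]
        seed = sp.get("seed", {}) or {}
        non = sp.get("nonseed", {}) or {}
        kw["specific"] = SpecificBudgets(
            seed=RegionBudgets(
                max_mm=seed.get("max-mm", settings.specific.seed.max_mm),
                max_ins=seed.get("max-ins", settings.specific.seed.max_ins),
                max_del=seed.get("max-del", settings.specific.seed.max_del),
            ),
            nonseed=RegionBudgets(
                max_mm=non.get("max-mm", settings.specific.nonseed.max_mm),
                max_ins=non.get("max-ins", settings.specific.nonseed.max_ins),
                max_del=non.get("max-del", settings.specific.nonseed.max_del),
            ),
        )
    return replace(settings, **kw)
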