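"""Score panel: the file-backed reference defining the 12-SNP / 6-SNP LDL-C score.

The panel holds, for each of the ten directly weighted SNPs, the LDL-raising
(risk) allele, its published per-allele weight, the short-panel membership
flag, and minor-allele frequencies in three study groups (a population
control cohort and familial-hypercholesterolemia cohorts with and without an
identified causative variant).  The two *APOE* epsilon-defining SNPs
(rs429358, rs7412) are panel members without per-allele weights; all APOE
contribution flows through a six-level diplotype weight table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "Group",
    "ScoreVariant",
    "ApoeDiplotypeWeights",
    "ScorePanel",
    "PanelError",
    "PanelSchemaError",
    "PanelValidationError",
    "APOE_RSIDS",
    "DIPLOTYPES",
    "load_panel",
    "write_panel",
    "default_panel_path",
]

APOE_RSIDS = ("rs429358", "rs7412")
DIPLOTYPES = ("E2E2", "E2E3", "E2E4", "E3E3", "E3E4", "E4E4")
NUCLEOTIDES = frozenset("ACGT")

_VARIANT_COLUMNS = [
    "rsid", "gene", "risk_allele", "other_allele", "weight", "in_6snp",
    "risk_is_minor", "maf_control", "maf_fh_neg", "maf_fh_pos",
]
_DIPLO_COLUMNS = ["diplotype", "weight", "freq_control", "freq_fh_neg", "freq_fh_pos"]


class Group(str, enum.Enum):
    """Study group labels: population controls and the two FH mutation strata."""

    CONTROL = "CONTROL"
    FH_M_NEG = "FH_M_NEG"
    FH_M_POS = "FH_M_POS"

    @classmethod
    def parse(cls, value: "Group | str") -> "Group":
        if isinstance(value, Group):
            return value
        key = str(value).strip().upper().replace("-", "_").replace("/", "_")
        aliases = {
            "CONTROL": cls.CONTROL,
            "CTRL": cls.CONTROL,
            "FH_M_NEG": cls.FH_M_NEG,
            "FH_NEG": cls.FH_M_NEG,
            "FH_M_": cls.FH_M_NEG,
            "FH_MINUS": cls.FH_M_NEG,
            "FH_M_POS": cls.FH_M_POS,
            "FH_POS": cls.FH_M_POS,
            "FH_M+": cls.FH_M_POS,
            "FH_PLUS": cls.FH_M_POS,
        }
        try:
            return aliases[key]
        except KeyError:
            raise PanelError(f"unknown group label: {value!r}") from None


_GROUP_SUFFIX = {Group.CONTROL: "control", Group.FH_M_NEG: "fh_neg", Group.FH_M_POS: "fh_pos"}


class PanelError(ValueError):
    """Base class for panel loading/validation problems."""


class PanelSchemaError(PanelError):
    """A required field or section is missing or unparseable."""


class PanelValidationError(PanelError):
    """The file parsed but violates a panel invariant."""


@dataclass(frozen=True)
class ScoreVariant:
    """One panel SNP: risk-allele orientation, weight and per-group MAF."""

    rsid: str
    gene: str
    risk_allele: str
    other_allele: str
    weight: float | None  # score units per risk allele; None for APOE SNPs
    in_6snp: bool
    risk_is_minor: bool
    group_maf: Mapping[Group, float]

    @property
    def is_apoe(self) -> bool:
        return self.rsid in APOE_RSIDS

    def risk_allele_frequency(self, group: Group | str) -> float:
        """Frequency of the risk allele: MAF if the risk allele is minor, else 1 - MAF."""
        group = Group.parse(group)
        if group not in self.group_maf:
            raise PanelError(f"{self.rsid}: no frequency for group {group.value}")
        maf = self.group_maf[group]
        return maf if self.risk_is_minor else 1.0 - maf


@dataclass(frozen=True)
class ApoeDiplotypeWeights:
    """Weights and per-group frequencies for the six APOE epsilon diplotypes.

    Diplotypes are unordered (E2E4 and E4E2 are the same class); keys use the
    canonical sorted form E2E2 .. E4E4.
    """

    weights: Mapping[str, float]
    group_freq: Mapping[Group, Mapping[str, float]]

    def weight(self, diplotype: str) -> float:
        d = canonical_diplotype(diplotype)
        return self.weights[d]

    def frequencies(self, group: Group | str, normalized: bool = False) -> dict[str, float]:
        group = Group.parse(group)
        if group not in self.group_freq:
            raise PanelError(f"no APOE diplotype frequencies for group {group.value}")
        freqs = dict(self.group_freq[group])
        if normalized:
            total = sum(freqs.values())
            if total <= 0:
                raise PanelError(f"APOE diplotype frequencies for {group.value} sum to 0")
            freqs = {k: v / total for k, v in freqs.items()}
        return freqs

    def mean_weight(self, group: Group | str, normalized: bool = False) -> float:
        freqs = self.frequencies(group, normalized=normalized)
        return sum(freqs[d] * self.weights[d] for d in DIPLOTYPES)


def canonical_diplotype(diplotype: str) -> str:
    """Normalize a diplotype label to its sorted form (E4E2 -> E2E4)."""
    d = diplotype.strip().upper()
    if len(d) == 4 and d[:2] in ("E2", "E3", "E4") and d[2:] in ("E2", "E3", "E4"):
        a, b = sorted((d[:2], d[2:]))
        return a + b
    raise PanelError(f"not an APOE diplotype label: {diplotype!r}")


@dataclass(frozen=True)
class ScorePanel:
    """The full 12-variant score definition plus the APOE diplotype table."""

    variants: tuple[ScoreVariant, ...]
    apoe: ApoeDiplotypeWeights
    panel_version: str = "unversioned"
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {v.rsid: v for v in self.variants})

    # -- access -----------------------------------------------------------
    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(v.rsid for v in self.variants)

    @property
    def snp_variants(self) -> tuple[ScoreVariant, ...]:
        """The directly weighted (non-APOE) variants, in panel order."""
        return tuple(v for v in self.variants if not v.is_apoe)

    def weighted_variants(self, panel_size: int = 12) -> tuple[ScoreVariant, ...]:
        """Non-APOE variants entering the weighted sum for a 12- or 6-SNP score."""
        if panel_size not in (12, 6):
            raise PanelError(f"panel_size must be 12 or 6, got {panel_size!r}")
        snps = self.snp_variants
        if panel_size == 6:
            snps = tuple(v for v in snps if v.in_6snp)
        return snps

    def variant(self, rsid: str) -> ScoreVariant:
        try:
            return self._index[rsid]
        except KeyError:
            raise PanelError(f"rsid not in panel: {rsid}") from None

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def risk_allele_frequency(self, rsid: str, group: Group | str) -> float:
        v = self.variant(rsid)
        if v.is_apoe:
            raise PanelError(
                f"{rsid} is an APOE SNP; its contribution is diplotypic, "
                "not a per-allele risk frequency"
            )
        return v.risk_allele_frequency(group)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if len(self.variants) != 12:
            raise PanelValidationError(
                f"panel must have exactly 12 variant entries, found {len(self.variants)}"
            )
        seen = set()
        for v in self.variants:
            if v.rsid in seen:
                raise PanelValidationError(f"duplicate rsid: {v.rsid}")
            seen.add(v.rsid)
            if v.risk_allele not in NUCLEOTIDES or v.other_allele not in NUCLEOTIDES:
                raise PanelValidationError(f"{v.rsid}: alleles must be A/C/G/T")
            if v.risk_allele == v.other_allele:
                raise PanelValidationError(f"{v.rsid}: risk and other allele are identical")
            if v.is_apoe:
                if v.weight is not None:
                    raise PanelValidationError(f"{v.rsid}: APOE SNPs carry no per-allele weight")
            else:
                if v.weight is None or not math.isfinite(v.weight) or v.weight < 0:
                    raise PanelValidationError(f"{v.rsid}: weight must be a finite value >= 0")
            for g, maf in v.group_maf.items():
                if not (0.0 <= maf <= 0.5 + 1e-9):
                    raise PanelValidationError(
                        f"{v.rsid}: MAF for {Group.parse(g).value} out of [0, 0.5]: {maf}"
                    )
        for rsid in APOE_RSIDS:
            if rsid not in seen:
                raise PanelValidationError(f"panel must include APOE SNP {rsid}")
        flagged = {v.rsid for v in self.variants if v.in_6snp}
        if len(flagged) != 6:
            raise PanelValidationError(
                f"exactly 6 variants must be flagged for the short panel, found {len(flagged)}"
            )
        if set(self.apoe.weights) != set(DIPLOTYPES):
            raise PanelValidationError("APOE weight table must cover the six diplotypes")
        if self.apoe.weights["E3E3"] != 0.0:
            raise PanelValidationError("E3E3 is the APOE reference diplotype; weight must be 0")
        for g, freqs in self.apoe.group_freq.items():
            for d, f in freqs.items():
                if not (0.0 <= f <= 1.0):
                    raise PanelValidationError(
                        f"APOE diplotype frequency out of [0,1]: {d} in {Group.parse(g).value}"
                    )


# -- file format ------------------------------------------------------------

def default_panel_path() -> Path:
    return Path(resources.files("fhprs.data") / "ldl_prs_panel.tsv")


def _parse_bool(s: str, where: str) -> bool:
    v = s.strip().lower()
    if v in ("yes", "true", "1"):
        return True
    if v in ("no", "false", "0"):
        return False
    raise PanelSchemaError(f"{where}: not a yes/no value: {s!r}")


def _parse_weight(s: str, where: str) -> float | None:
    v = s.strip()
    if v.upper() in ("NA", "", "-", "."):
        return None
    try:
        return float(v)
    except ValueError:
        raise PanelSchemaError(f"{where}: not a numeric weight: {s!r}") from None


def _parse_float(s: str, where: str) -> float:
    try:
        return float(s)
    except ValueError:
        raise PanelSchemaError(f"{where}: not a number: {s!r}") from None


def load_panel(path: str | Path | None = None) -> ScorePanel:
    """Load and validate a score panel file (the packaged default when path is None).

    The format is a sectioned tab-separated text file with ``[panel]``,
    ``[variants]`` and ``[apoe_diplotypes]`` sections; ``#`` lines are comments.
    """
    path = default_panel_path() if path is None else Path(path)
    if not path.exists():
        raise PanelError(f"panel file not found: {path}")

    section = None
    header: list[str] | None = None
    version = "unversioned"
    variants: list[ScoreVariant] = []
    weights: dict[str, float] = {}
    freqs: dict[Group, dict[str, float]] = {g: {} for g in Group}

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("[") and line.rstrip().endswith("]"):
            section = line.strip()[1:-1].strip().lower()
            header = None
            continue
        fields = line.split("\t")
        where = f"{path.name}:{lineno}"
        if section == "panel":
            if len(fields) >= 2 and fields[0].strip() == "version":
                version = fields[1].strip()
            continue
        if section == "variants":
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in _VARIANT_COLUMNS if c not in header]
                if missing:
                    raise PanelSchemaError(
                        f"{where}: [variants] header missing field(s): {', '.join(missing)}"
                    )
                continue
            row = dict(zip(header, fields))
            for col in _VARIANT_COLUMNS:
                if col not in row or row[col].strip() == "":
                    raise PanelSchemaError(f"{where}: missing field {col!r}")
            variants.append(
                ScoreVariant(
                    rsid=row["rsid"].strip(),
                    gene=row["gene"].strip(),
                    risk_allele=row["risk_allele"].strip().upper(),
                    other_allele=row["other_allele"].strip().upper(),
                    weight=_parse_weight(row["weight"], where),
                    in_6snp=_parse_bool(row["in_6snp"], where),
                    risk_is_minor=_parse_bool(row["risk_is_minor"], where),
                    group_maf={
                        g: _parse_float(row[f"maf_{_GROUP_SUFFIX[g]}"], where) for g in Group
                    },
                )
            )
            continue
        if section == "apoe_diplotypes":
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in _DIPLO_COLUMNS if c not in header]
                if missing:
                    raise PanelSchemaError(
                        f"{where}: [apoe_diplotypes] header missing field(s): {', '.join(missing)}"
                    )
                continue
            row = dict(zip(header, fields))
            for col in _DIPLO_COLUMNS:
                if col not in row or row[col].strip() == "":
                    raise PanelSchemaError(f"{where}: missing field {col!r}")
            d = canonical_diplotype(row["diplotype"])
            weights[d] = _parse_float(row["weight"], where)
            for g in Group:
                freqs[g][d] = _parse_float(row[f"freq_{_GROUP_SUFFIX[g]}"], where)
            continue
        raise PanelSchemaError(f"{where}: content outside a recognized section")

    if not variants:
        raise PanelSchemaError(f"{path}: no [variants] section")
    if not weights:
        raise PanelSchemaError(f"{path}: no [apoe_diplotypes] section")

    panel = ScorePanel(
        variants=tuple(variants),
        apoe=ApoeDiplotypeWeights(weights=weights, group_freq={g: f for g, f in freqs.items()}),
        panel_version=version,
    )
    panel.validate()
    return panel


def write_panel(panel: ScorePanel, path: str | Path) -> Path:
    """Write a panel in the same sectioned format load_panel reads (round-trips)."""
    path = Path(path)
    lines = ["[panel]", f"version\t{panel.panel_version}", "[variants]",
             "\t".join(_VARIANT_COLUMNS)]
    for v in panel.variants:
        lines.append("\t".join([
            v.rsid, v.gene, v.risk_allele, v.other_allele,
            "NA" if v.weight is None else format(v.weight, "g"),
            "yes" if v.in_6snp else "no",
            "yes" if v.risk_is_minor else "no",
            *(format(v.group_maf[g], "g") for g in Group),
        ]))
    lines.append("[apoe_diplotypes]")
    lines.append("\t".join(_DIPLO_COLUMNS))
    for d in DIPLOTYPES:
        lines.append("\t".join([
            d, format(panel.apoe.weights[d], "g"),
            *(format(panel.apoe.group_freq[g][d], "g") for g in Group),
        ]))
    path.write_text("\n".join(lines) + "\n")
    return path
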