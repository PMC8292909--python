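"""Compound library standardization and filtering.

Raw vendor records (SMILES/SDF) are standardized — salt/counter-ion stripping,
isotope clearing, charge neutralization, canonical aromatic form — and then
passed through drug-likeness property filters (molecular weight 100–700 Da,
≤6 stereocenters, ≤60 atoms including hydrogens, ≤15 rotatable bonds, element
whitelist C/N/S/H/O/P/B/halogens) and substructure exclusion rules (PAINS plus
small toxicophore / medicinal-chemistry stand-in sets).

All property bounds are inclusive.  "Halogens" means F, Cl, Br, I.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

ALLOWED_ELEMENTS = frozenset({"C", "N", "S", "H", "O", "P", "B", "F", "Cl", "Br", "I"})

# Small documented stand-in rule sets; the vendor's exact toxicophore and
# medchem collections are not public.  Fully configurable via FilterConfig.
TOXICOPHORE_SMARTS = {
    "nitroso": "[#6]N=O",
    "azo_aromatic": "c/N=N/c",
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "isocyanate": "[NX2]=C=O",
    "aldehyde_michael": "[CX3H1](=O)C=C",
}
MEDCHEM_SMARTS = {
    "peroxide": "[OX2][OX2]",
    "thiourea": "[NX3][CX3](=S)[NX3]",
    "hydrazine": "[NX3][NX3]",
    "phosphonate_ester": "P(=O)(O[#6])O[#6]",
}


@dataclass(frozen=True)
class Molecule:
    """A standardized small molecule (RDKit mol + provenance)."""

    id: str
    mol: Chem.Mol
    source_line: str = ""

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass(frozen=True)
class DescriptorSet:
    mw: float
    n_atoms: int
    n_rotatable: int
    n_chiral: int
    elements: frozenset

    def __post_init__(self):
        if self.mw <= 0 or min(self.n_atoms, self.n_rotatable, self.n_chiral) < 0:
            raise ValueError("invalid descriptor set")


@dataclass
class FilterConfig:
    mw_min: float = 100.0
    mw_max: float = 700.0
    max_chiral: int = 6
    max_atoms: int = 60
    max_rotatable: int = 15
    count_hydrogens: bool = True
    allowed_elements: frozenset = ALLOWED_ELEMENTS
    use_pains: bool = True
    use_toxicophores: bool = True
    use_medchem: bool = True
    extra_smarts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mw_min >= self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if min(self.max_chiral, self.max_atoms, self.max_rotatable) < 0:
            raise ValueError("property maxima must be >= 0")

    @classmethod
    def from_json(cls, path) -> "FilterConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "allowed_elements" in raw:
            raw["allowed_elements"] = frozenset(raw["allowed_elements"])
        return cls(**raw)


@dataclass
class FilterReport:
    n_input: int = 0
    n_standardized: int = 0
    n_pass_property: int = 0
    n_surviving: int = 0
    rejections: dict = field(default_factory=dict)  # id -> list of reasons
    valid: bool = True

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


class StandardizationError(ValueError):
    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


_UNCHARGER = rdMolStandardize.Uncharger()


def standardize(raw, mol_id: str = "", source_line: str = "") -> Molecule:
    """Standardize a raw record: keep the largest organic fragment, clear
    isotope labels, neutralize charges where a protonation change permits,
    and emit one canonical aromatic form.  Idempotent.

    ``raw`` may be a SMILES string, an RDKit mol, or a Molecule.
    """
    if isinstance(raw, Molecule):
        mol, mol_id = raw.mol, mol_id or raw.id
        source_line = source_line or raw.source_line
    elif isinstance(raw, Chem.Mol):
        mol = raw
    else:
        if not isinstance(raw, str) or not raw.strip():
            raise StandardizationError("empty")
        source_line = source_line or raw
        mol = Chem.MolFromSmiles(raw)
        if mol is None:
            raise StandardizationError("parse_error")
    if mol is None or mol.GetNumAtoms() == 0:
        raise StandardizationError("empty")
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = rdMolStandardize.FragmentParent(mol)  # largest organic fragment
        mol = _UNCHARGER.uncharge(mol)
    except Exception:
        raise StandardizationError("parse_error")
    if mol is None or mol.GetNumAtoms() == 0:
        raise StandardizationError("empty")
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    # round-trip through canonical SMILES so aromatic rings and functional
    # groups are written in one consistent representation
    smi = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise StandardizationError("parse_error")
    return Molecule(id=mol_id, mol=mol, source_line=source_line)


_AMIDE = Chem.MolFromSmarts("[NX3][CX3](=[OX1])")


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Non-ring single bonds between two heavy atoms that each carry at least
    one additional heavy neighbor, excluding amide C–N bonds."""
    amide_pairs = {frozenset(m[:2]) for m in mol.GetSubstructMatches(_AMIDE)}
    n = 0
    for b in mol.GetBonds():
        if b.GetBondType() != Chem.BondType.SINGLE or b.IsInRing():
            continue
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        if a1.GetDegree() < 2 or a2.GetDegree() < 2:
            continue  # terminal heavy atom
        if frozenset((a1.GetIdx(), a2.GetIdx())) in amide_pairs:
            continue
        n += 1
    return n


def compute_descriptors(mol: Molecule | Chem.Mol, count_hydrogens: bool = True) -> DescriptorSet:
    """Descriptors used by the property filters.

    mw sums standard atomic masses including implicit hydrogens; n_atoms counts
    hydrogens by default (configurable); n_chiral counts assigned and
    unassigned stereocenters.
    """
    m = mol.mol if isinstance(mol, Molecule) else mol
    mh = Chem.AddHs(m)
    n_atoms = mh.GetNumAtoms() if count_hydrogens else m.GetNumAtoms()
    chiral = Chem.FindMolChiralCenters(m, includeUnassigned=True, useLegacyImplementation=False)
    elements = frozenset(a.GetSymbol() for a in mh.GetAtoms())
    return DescriptorSet(
        mw=Descriptors.MolWt(m),
        n_atoms=n_atoms,
        n_rotatable=count_rotatable_bonds(m),
        n_chiral=len(chiral),
        elements=elements,
    )


def apply_property_filters(desc: DescriptorSet, cfg: FilterConfig | None = None):
    """Return (passed, reasons).  All bounds inclusive."""
    cfg = cfg or FilterConfig()
    reasons = []
    if desc.mw < cfg.mw_min:
        reasons.append("mw_below_min")
    if desc.mw > cfg.mw_max:
        reasons.append("mw_above_max")
    if desc.n_chiral > cfg.max_chiral:
        reasons.append("too_many_chiral")
    if desc.n_atoms > cfg.max_atoms:
        reasons.append("too_many_atoms")
    if desc.n_rotatable > cfg.max_rotatable:
        reasons.append("too_many_rotatable")
    if not desc.elements <= cfg.allowed_elements:
        reasons.append("element_not_allowed")
    return (not reasons), reasons


class SubstructureFilter:
    """Named SMARTS rule collections (PAINS via the published catalog families
    plus shipped toxicophore/medchem stand-ins).  Malformed SMARTS raise at
    load time, not per molecule."""

    def __init__(self, cfg: FilterConfig | None = None):
        cfg = cfg or FilterConfig()
        self._catalog = None
        if cfg.use_pains:
            params = FilterCatalogParams()
            params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
            self._catalog = FilterCatalog(params)
        self._patterns = {}
        named = {}
        if cfg.use_toxicophores:
            named.update({f"toxicophore:{k}": v for k, v in TOXICOPHORE_SMARTS.items()})
        if cfg.use_medchem:
            named.update({f"medchem:{k}": v for k, v in MEDCHEM_SMARTS.items()})
        named.update(cfg.extra_smarts)
        for name, smarts in named.items():
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"malformed SMARTS for rule {name!r}: {smarts}")
            self._patterns[name] = patt

    def matches(self, mol: Molecule | Chem.Mol) -> list[str]:
        m = mol.mol if isinstance(mol, Molecule) else mol
        hits = []
        if self._catalog is not None:
            for entry in self._catalog.GetMatches(m):
                hits.append(f"PAINS:{entry.GetDescription()}")
        for name, patt in self._patterns.items():
            if m.HasSubstructMatch(patt):
                hits.append(name)
        return sorted(hits)


def apply_substructure_filters(mol, cfg: FilterConfig | None = None,
                               filt: SubstructureFilter | None = None):
    filt = filt or SubstructureFilter(cfg)
    hits = filt.matches(mol)
    return (not hits), hits


def filter_library(records: Iterable[tuple[str, str]], cfg: FilterConfig | None = None
                   ) -> tuple[list[Molecule], FilterReport]:
    """Run the full pipeline standardize → property → substructure.

    ``records`` yields (id, smiles).  Survivor order follows input order.
    """
    cfg = cfg or FilterConfig()
    sub = SubstructureFilter(cfg)
    report = FilterReport()
    survivors: list[Molecule] = []
    for mol_id, smi in records:
        report.n_input += 1
        try:
            mol = standardize(smi, mol_id=mol_id)
        except StandardizationError as e:
            report.rejections[mol_id] = [e.reason]
            continue
        report.n_standardized += 1
        desc = compute_descriptors(mol, count_hydrogens=cfg.count_hydrogens)
        ok, reasons = apply_property_filters(desc, cfg)
        if not ok:
            report.rejections[mol_id] = reasons
            continue
        report.n_pass_property += 1
        ok, hits = apply_substructure_filters(mol, filt=sub)
        if not ok:
            report.rejections[mol_id] = hits
            continue
        survivors.append(mol)
    report.n_surviving = len(survivors)
    return survivors, report


def read_smiles_file(path) -> Iterator[tuple[str, str]]:
    """One record per line: SMILES [whitespace id]."""
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            yield mol_id, smi


def write_smiles_file(path, mols: Iterable[Molecule]) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{m.smiles}\t{m.id}\n")
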