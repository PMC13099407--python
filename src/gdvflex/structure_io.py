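"""Reading, filtering and writing of PDB structural models.

Atoms are kept in file order in an :class:`AtomTable` (a thin wrapper around a
pandas DataFrame).  Multi-model files (NMR ensembles, trajectory frames dumped
as MODEL/ENDMDL blocks) become an :class:`Ensemble`.  Per-atom scalar output
(predicted or reference RMSF) travels in the B-factor column, the convention
used by cryo-EM flexibility benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateInputError,
    ModelNotFoundError,
    StructureFormatError,
)

#: The 20 standard amino-acid residue names retained by the protein filter.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})

_COLUMNS = [
    "serial",
    "atom_name",
    "alt_loc",
    "res_name",
    "chain_id",
    "res_seq",
    "insertion_code",
    "x",
    "y",
    "z",
    "occupancy",
    "b_value",
    "element",
    "record",
]


@dataclass
class AtomTable:
    """Ordered per-atom records for one structural model."""

    df: pd.DataFrame
    model_id: int = 1

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"AtomTable missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_atoms(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        """Cartesian coordinates, shape (N, 3), Å."""
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    def with_coords(self, coords: np.ndarray) -> "AtomTable":
        df = self.df.copy()
        df[["x", "y", "z"]] = np.asarray(coords, dtype=float)
        return AtomTable(df, model_id=self.model_id)

    @property
    def ca_mask(self) -> np.ndarray:
        """Boolean mask of alpha-carbon atoms (one per residue in proteins)."""
        return (self.df["atom_name"].to_numpy() == "CA") & (
            self.df["element"].to_numpy() != "CA"
        )

    @property
    def residue_ids(self) -> np.ndarray:
        """Integer residue code per atom, in order of first appearance."""
        key = pd.Series(
            list(
                zip(
                    self.df["chain_id"],
                    self.df["res_seq"],
                    self.df["insertion_code"],
                )
            )
        )
        codes, _ = pd.factorize(key, use_na_sentinel=False)
        return codes

    @property
    def n_residues(self) -> int:
        return int(self.residue_ids.max()) + 1 if len(self.df) else 0

    def identity_tuples(self) -> list[tuple]:
        """(chain, res_seq, icode, atom_name) per atom — roster identity."""
        return list(
            zip(
                self.df["chain_id"],
                self.df["res_seq"],
                self.df["insertion_code"],
                self.df["atom_name"],
            )
        )


@dataclass
class Ensemble:
    """A list of models sharing one atom roster, index by index."""

    models: list[AtomTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise DegenerateInputError("ensemble with no models")
        ref = self.models[0].identity_tuples()
        for m in self.models[1:]:
            if m.identity_tuples() != ref:
                raise AlignmentError(
                    "ensemble models do not share an identical atom roster"
                )

    def __len__(self) -> int:
        return len(self.models)

    @property
    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_models, N, 3)."""
        return np.stack([m.coords for m in self.models])


def _model_num(model: gemmi.Model) -> int:
    num = getattr(model, "num", None)
    if num is None:  # older gemmi kept the number in .name
        num = int(model.name)
    return int(num)


def _model_to_table(model: gemmi.Model) -> AtomTable:
    rows = []
    for chain in model:
        for res in chain:
            het = res.het_flag
            record = "HETATM" if het == "H" else "ATOM"
            icode = res.seqid.icode.strip()
            for atom in res:
                alt = atom.altloc
                if alt in ("\x00", " "):
                    alt = ""
                rows.append(
                    (
                        atom.serial,
                        atom.name,
                        alt,
                        res.name,
                        chain.name,
                        res.seqid.num,
                        icode,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.occ,
                        atom.b_iso,
                        atom.element.name.upper(),
                        record,
                    )
                )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return AtomTable(df, model_id=_model_num(model))


def read_structure(
    path: Union[str, Path], model: Union[int, str] = 1
) -> Union[AtomTable, Ensemble]:
    """Read a PDB file.

    Parameters
    ----------
    path:
        PDB file path.
    model:
        1-based model number to extract, or ``"all"`` for an :class:`Ensemble`
        of every model in the file.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or sum(ch.count_atom_sites() for m in st for ch in m) == 0:
        raise StructureFormatError(f"no atoms found in {path}")
    if model == "all":
        return Ensemble([_model_to_table(m) for m in st])
    for m in st:
        if _model_num(m) == int(model):
            return _model_to_table(m)
    raise ModelNotFoundError(f"model {model} not present in {path}")


def filter_protein_heavy(atoms: AtomTable) -> AtomTable:
    """Keep heavy (non-hydrogen) atoms of standard amino-acid ATOM records.

    Waters, hetero compounds and hydrogens are dropped.  Among alternate
    locations of one atom the highest-occupancy conformer is kept (ties go to
    the first encountered).  Idempotent.
    """
    df = atoms.df
    keep = (
        (df["record"] == "ATOM")
        & df["res_name"].isin(STANDARD_AA)
        & ~df["element"].isin(_HYDROGEN_ELEMENTS)
    )
    df = df[keep]
    if len(df):
        grp = df.groupby(
            ["chain_id", "res_seq", "insertion_code", "atom_name"], sort=False
        )["occupancy"]
        # idxmax is stable: the first occurrence of the maximum wins the tie
        df = df.loc[sorted(grp.idxmax())]
    if not len(df):
        raise DegenerateInputError("no protein heavy atoms left after filtering")
    return AtomTable(df.reset_index(drop=True), model_id=atoms.model_id)


B_VALUE_MIN = -99.99
B_VALUE_MAX = 999.99


def _to_gemmi(tables: Sequence[AtomTable], name: str = "gdvflex") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for k, table in enumerate(tables, start=1):
        model = gemmi.Model(k)
        chain = None
        res = None
        last_key = None
        for row in table.df.itertuples(index=False):
            if chain is None or chain.name != row.chain_id:
                chain = gemmi.Chain(row.chain_id)
                model.add_chain(chain)
                chain = model[-1]
                last_key = None
            key = (row.res_seq, row.insertion_code, row.res_name)
            if key != last_key:
                res = gemmi.Residue()
                res.name = row.res_name
                res.seqid = gemmi.SeqId(int(row.res_seq), row.insertion_code or " ")
                res.het_flag = "H" if row.record == "HETATM" else "A"
                chain.add_residue(res)
                res = chain[-1]
                last_key = key
            atom = gemmi.Atom()
            atom.name = row.atom_name
            atom.altloc = row.alt_loc if row.alt_loc else "\x00"
            atom.serial = int(row.serial)
            atom.pos = gemmi.Position(row.x, row.y, row.z)
            atom.occ = float(row.occupancy)
            b = float(row.b_value)
            if not math.isnan(b):
                b = min(max(b, B_VALUE_MIN), B_VALUE_MAX)
            atom.b_iso = b
            atom.element = gemmi.Element(row.element)
            res.add_atom(atom)
        st.add_model(model)
    return st


def write_structure(
    structure: Union[AtomTable, Ensemble], path: Union[str, Path]
) -> None:
    """Write an AtomTable (or multi-model Ensemble) as a PDB file."""
    tables = structure.models if isinstance(structure, Ensemble) else [structure]
    st = _to_gemmi(tables)
    st.write_pdb(str(path))


def write_predictions(
    atoms: AtomTable,
    values: Union[np.ndarray, Iterable[float]],
    path: Union[str, Path],
) -> None:
    """Write ``atoms`` as PDB with ``values`` in the B-factor column.

    Values are clamped to the fixed-width field range [-99.99, 999.99].
    """
    values = np.asarray(
        getattr(values, "values", values), dtype=float
    )  # accepts RMSFProfile
    if values.shape != (atoms.n_atoms,):
        raise AlignmentError(
            f"got {values.shape[0] if values.ndim else 'scalar'} values "
            f"for {atoms.n_atoms} atoms"
        )
    df = atoms.df.copy()
    df["b_value"] = np.clip(values, B_VALUE_MIN, B_VALUE_MAX)
    write_structure(AtomTable(df, model_id=atoms.model_id), path)


def radius_of_gyration(atoms: AtomTable) -> float:
    """Mass-unweighted Rg: RMS distance of atoms from their centroid (Å)."""
    if atoms.n_atoms == 0:
        raise DegenerateInputError("radius of gyration of an empty atom table")
    xyz = atoms.coords
    delta = xyz - xyz.mean(axis=0)
    return float(np.sqrt((delta**2).sum(axis=1).mean()))


@dataclass(frozen=True)
class GlobularityResult:
    """Outcome of the globular-shape filter Rg < N^0.6 (N = residue count)."""

    is_globular: bool
    rg: float
    n_residues: int
    threshold: float
    length_ok: bool  # N > 50, the companion size filter

    def __bool__(self) -> bool:
        return self.is_globular


def globularity_check(atoms: AtomTable, min_residues: int = 50) -> GlobularityResult:
    """Check the compactness filter Rg < N**0.6 and the size filter N > 50."""
    rg = radius_of_gyration(atoms)
    n_res = atoms.n_residues
    threshold = float(n_res) ** 0.6
    return GlobularityResult(
        is_globular=rg < threshold,
        rg=rg,
        n_residues=n_res,
        threshold=threshold,
        length_ok=n_res > min_residues,
    )
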