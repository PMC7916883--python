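"""Protein structure I/O, selections, and residue-numbering maps.

This module owns the static-structure side of the pipeline: reading and
writing fixed-column PDB, extracting sequences and C-alpha traces, defining
named functional regions on a dimer (active-site floor/walls/roof and the
cofactor sites of serine hydroxymethyltransferase), and mapping residue
numbering between homologous structures through a pairwise sequence
alignment.

Coordinates are stored in Angstrom, exactly as PDB prints them; trajectory
analytics convert to nm at the boundary (see :mod:`mdcompare.trajectory`).
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.SeqUtils import seq1

__all__ = [
    "Structure",
    "PairwiseAlignment",
    "ResidueMap",
    "Region",
    "RegionSet",
    "read_structure",
    "write_structure",
    "pairwise_align",
    "map_residue_numbering",
    "shmt_region_set",
]

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class Structure:
    """An atomic model as parallel per-atom arrays (coordinates in Angstrom).

    Atom identity is the (chain id, residue number, insertion code) triple
    plus the atom name; residue numbering is the author numbering of the
    source PDB and is never rewritten.
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resnums: np.ndarray
    icodes: np.ndarray
    chain_ids: np.ndarray
    occupancies: np.ndarray
    coords: np.ndarray
    is_hetatm: np.ndarray
    title: str = ""

    def __post_init__(self) -> None:
        n = len(self.names)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        for arr_name in ("elements", "resnames", "resnums", "icodes", "chain_ids",
                         "occupancies", "is_hetatm"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"field {arr_name!r} length mismatch (expected {n})")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def select(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        return Structure(
            names=self.names[mask],
            elements=self.elements[mask],
            resnames=self.resnames[mask],
            resnums=self.resnums[mask],
            icodes=self.icodes[mask],
            chain_ids=self.chain_ids[mask],
            occupancies=self.occupancies[mask],
            coords=self.coords[mask],
            is_hetatm=self.is_hetatm[mask],
            title=self.title,
        )

    def chain_mask(self, chains: str | list[str]) -> np.ndarray:
        if isinstance(chains, str):
            chains = [chains]
        return np.isin(self.chain_ids, list(chains))

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resnum, icode) triples of polymer residues."""
        keys: dict[tuple[str, int, str], None] = {}
        for i in range(self.n_atoms):
            if self.is_hetatm[i]:
                continue
            keys.setdefault(
                (str(self.chain_ids[i]), int(self.resnums[i]), str(self.icodes[i])), None
            )
        return list(keys)

    def ca_indices(self, chains: str | list[str] | None = None) -> np.ndarray:
        """Indices of CA atoms of standard amino-acid residues (one per residue)."""
        mask = (self.names == "CA") & ~self.is_hetatm
        mask &= np.isin(self.resnames, list(STANDARD_AA))
        if chains is not None:
            mask &= self.chain_mask(chains)
        idx = np.nonzero(mask)[0]
        # one CA per (chain, resnum, icode): keep first occurrence
        seen: dict[tuple[str, int, str], int] = {}
        out = []
        for i in idx:
            key = (str(self.chain_ids[i]), int(self.resnums[i]), str(self.icodes[i]))
            if key not in seen:
                seen[key] = i
                out.append(i)
        return np.asarray(out, dtype=int)

    def ca_trace(self, chains: str | list[str] | None = None):
        """Return ([(chain, resnum), ...], coords in Angstrom) for the CA trace."""
        idx = self.ca_indices(chains)
        keys = [(str(self.chain_ids[i]), int(self.resnums[i])) for i in idx]
        return keys, self.coords[idx].copy()

    def sequence(self, chain: str) -> str:
        """One-letter sequence of a chain from its standard-residue CA order."""
        idx = self.ca_indices(chain)
        return "".join(seq1(str(self.resnames[i]).capitalize()) for i in idx)

    def residue_atom_indices(self, chain: str, resnum: int) -> np.ndarray:
        mask = (self.chain_ids == chain) & (self.resnums == resnum) & ~self.is_hetatm
        return np.nonzero(mask)[0]

    def has_residue(self, chain: str, resnum: int) -> bool:
        return bool(np.any((self.chain_ids == chain) & (self.resnums == resnum)
                           & ~self.is_hetatm))

    def numbering_gaps(self, chain: str) -> list[tuple[int, int]]:
        """Report jumps in author numbering, a proxy for unmodeled residues.

        Returns (last residue before the gap, first residue after it) pairs.
        The package does not rebuild missing residues; it only reports them.
        """
        idx = self.ca_indices(chain)
        nums = [int(self.resnums[i]) for i in idx]
        return [(a, b) for a, b in zip(nums, nums[1:]) if b - a > 1]

    def to_fasta(self) -> str:
        lines = []
        for c in self.chains:
            seq = self.sequence(c)
            if seq:
                lines.append(f">{self.title or 'structure'}|chain_{c}")
                lines.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
        return "\n".join(lines) + "\n"


def read_structure(pdb_text: str, chains_to_keep: list[str] | None = None) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL is read (multi-model files are trajectories; see
    :func:`mdcompare.trajectory.read_multimodel_pdb`).  Alternate locations
    are resolved to the highest-occupancy conformer, ties going to the
    altloc letter that appears first.  Residue numbering is preserved
    verbatim.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file.
    chains_to_keep:
        If given, restrict to these chain ids; an absent chain is an error.

    Raises
    ------
    ValueError
        If no ATOM record is present, a coordinate field is malformed
        (the message names the offending line), or a requested chain is
        missing.
    """
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        bio = parser.get_structure("s", io.StringIO(pdb_text))
    except PDBConstructionException as exc:  # strict parser names the line
        raise ValueError(f"malformed PDB record: {exc}") from exc
    try:
        model = next(bio.get_models())
    except StopIteration:
        raise ValueError("no ATOM records found in PDB text") from None

    names, elements, resnames, resnums, icodes = [], [], [], [], []
    chain_ids, occupancies, coords, is_het = [], [], [], []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            het = hetflag.strip() != ""
            if hetflag == "W":
                het = True
            for atom in residue:
                if atom.is_disordered():
                    atom = atom.disordered_get()  # highest occupancy, first on tie
                names.append(atom.get_name())
                elements.append((atom.element or "").strip().upper())
                resnames.append(residue.get_resname().strip())
                resnums.append(int(resseq))
                icodes.append(icode.strip())
                chain_ids.append(chain.id)
                occupancies.append(float(atom.get_occupancy() or 1.0))
                coords.append(atom.get_coord())
                is_het.append(het)

    if not names:
        raise ValueError("no ATOM records found in PDB text")

    structure = Structure(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resnums=np.array(resnums, dtype=int),
        icodes=np.array(icodes, dtype=object),
        chain_ids=np.array(chain_ids, dtype=object),
        occupancies=np.array(occupancies, dtype=float),
        coords=np.array(coords, dtype=float),
        is_hetatm=np.array(is_het, dtype=bool),
        title="",
    )
    if chains_to_keep is not None:
        present = set(structure.chains)
        missing = [c for c in chains_to_keep if c not in present]
        if missing:
            raise ValueError(
                f"requested chain(s) {missing} absent; present: {sorted(present)}"
            )
        structure = structure.select(structure.chain_mask(chains_to_keep))
    return structure


def _format_atom_name(name: str, element: str) -> str:
    """PDB atom-name column alignment: 1-letter elements start in column 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"
    return f" {name:<3}"


def write_structure(structure: Structure, model_number: int | None = None) -> str:
    """Serialize a :class:`Structure` to fixed-column PDB text.

    Coordinates are printed at the format's full precision (0.001 A), so a
    write/read round trip reproduces them exactly at that precision.
    """
    lines = []
    if model_number is not None:
        lines.append(f"MODEL     {model_number:4d}")
    serial = 0
    prev_chain = None
    for i in range(structure.n_atoms):
        chain = str(structure.chain_ids[i])
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        serial += 1
        record = "HETATM" if structure.is_hetatm[i] else "ATOM  "
        x, y, z = structure.coords[i]
        element = str(structure.elements[i])
        lines.append(
            f"{record}{serial % 100000:5d} "
            f"{_format_atom_name(str(structure.names[i]), element)}"
            f"{'':1}{str(structure.resnames[i]):>3} {chain:1}"
            f"{int(structure.resnums[i]) % 10000:4d}{str(structure.icodes[i]) or ' ':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{structure.occupancies[i]:6.2f}{0.0:6.2f}"
            f"          {element:>2}"
        )
    lines.append("TER")
    lines.append("ENDMDL" if model_number is not None else "END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pairwise sequence alignment and residue-number mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment with affine gaps.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings; percent
    identity counts identical residue pairs over columns that carry a
    residue on *both* sides (gap columns excluded from the denominator).
    """

    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def percent_identity(self) -> float:
        both = [(a, b) for a, b in zip(self.aligned_a, self.aligned_b)
                if a != "-" and b != "-"]
        if not both:
            return 0.0
        same = sum(a == b for a, b in both)
        return 100.0 * same / len(both)


def pairwise_align(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Global alignment of two amino-acid sequences (BLOSUM62, affine gaps).

    Defaults are the standard BLOSUM62 / open 10 / extend 0.5 scoring.
    Raises ``ValueError`` for empty input or characters outside the
    standard one-letter alphabet (the offending symbols are listed).
    """
    for label, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{label} is empty")
        bad = sorted({c for c in seq if c not in _AA_LETTERS})
        if bad:
            raise ValueError(f"{label} contains non-standard characters: {bad}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(
        seq_a=seq_a,
        seq_b=seq_b,
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=float(aln.score),
    )


@dataclass(frozen=True)
class ResidueMap:
    """One-to-one monotone correspondence between two residue numberings.

    ``pairs`` holds (number in A, number in B); ``matches`` flags identical
    residues at the aligned positions.
    """

    pairs: tuple[tuple[int, int], ...]
    matches: tuple[bool, ...]
    percent_identity: float

    def __post_init__(self) -> None:
        a_nums = [p[0] for p in self.pairs]
        b_nums = [p[1] for p in self.pairs]
        if sorted(a_nums) != a_nums or sorted(b_nums) != b_nums:
            raise ValueError("residue map must be monotone in both numberings")
        if len(set(a_nums)) != len(a_nums) or len(set(b_nums)) != len(b_nums):
            raise ValueError("residue map must be one-to-one")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity out of [0, 100]")

    def a_to_b(self) -> dict[int, int]:
        return {a: b for a, b in self.pairs}

    def b_to_a(self) -> dict[int, int]:
        return {b: a for a, b in self.pairs}


def map_residue_numbering(
    alignment: PairwiseAlignment,
    numbers_a: list[int] | None = None,
    numbers_b: list[int] | None = None,
) -> ResidueMap:
    """Turn an alignment into a residue-number map.

    Only columns with a residue on both sides produce pairs.  By default
    positions are 1-based sequence indices; pass ``numbers_a``/``numbers_b``
    (author residue numbers in sequence order, e.g. from a CA trace) to map
    between PDB numberings instead.
    """
    if numbers_a is not None and len(numbers_a) != len(alignment.seq_a):
        raise ValueError("numbers_a length must equal len(seq_a)")
    if numbers_b is not None and len(numbers_b) != len(alignment.seq_b):
        raise ValueError("numbers_b length must equal len(seq_b)")
    pairs, matches = [], []
    ia = ib = 0
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if ca != "-" and cb != "-":
            na = numbers_a[ia] if numbers_a is not None else ia + 1
            nb = numbers_b[ib] if numbers_b is not None else ib + 1
            pairs.append((int(na), int(nb)))
            matches.append(ca == cb)
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return ResidueMap(
        pairs=tuple(pairs),
        matches=tuple(matches),
        percent_identity=alignment.percent_identity,
    )


# ---------------------------------------------------------------------------
# Named functional regions on a two-monomer dimer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """Residues forming a named site, split by which monomer contributes them.

    ``own`` lists residue numbers in the monomer that owns the site;
    ``other`` lists residues contributed across the interface by the
    partner monomer.
    """

    name: str
    own: tuple[int, ...]
    other: tuple[int, ...] = ()


@dataclass(frozen=True)
class RegionSet:
    """A collection of named regions defined on a homodimer."""

    regions: tuple[Region, ...] = ()

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def resolve(
        self, structure: Structure, own_chain: str, other_chain: str
    ) -> dict[str, list[tuple[str, int]]]:
        """Materialize each region as (chain, residue number) pairs.

        Every listed residue must exist in the structure; a missing one is
        an error naming the residue.
        """
        out: dict[str, list[tuple[str, int]]] = {}
        for region in self.regions:
            members: list[tuple[str, int]] = []
            for chain, nums in ((own_chain, region.own), (other_chain, region.other)):
                for num in nums:
                    if not structure.has_residue(chain, num):
                        raise ValueError(
                            f"region {region.name!r}: residue {num} not found in "
                            f"chain {chain!r}"
                        )
                    members.append((chain, num))
            out[region.name] = members
        return out


def _interval(a: int, b: int) -> tuple[int, ...]:
    return tuple(range(a, b + 1))


def shmt_region_set() -> RegionSet:
    """Functional regions of the SHMT dimer, in the mesophilic numbering.

    The active-site cavity decomposes into a floor (beta-strands 6-8 plus
    connecting loops, residues 197-204 and 213-242), an inner wall (helix
    alpha-6, 97-110, completed by loop 258-264 of the partner monomer), an
    outer wall (loop 174-182), and a roof (loop 118-133).  The cofactor
    (PLP) and folate sites straddle the interface, so both list partner
    residues.  ``walls`` combines inner and outer wall for site-level
    flexibility summaries.
    """
    inner_own = _interval(97, 110)
    inner_other = _interval(258, 264)
    outer_own = _interval(174, 182)
    return RegionSet(regions=(
        Region("floor", own=_interval(197, 204) + _interval(213, 242)),
        Region("inner_wall", own=inner_own, other=inner_other),
        Region("outer_wall", own=outer_own),
        Region("walls", own=inner_own + outer_own, other=inner_other),
        Region("roof", own=_interval(118, 133)),
        Region("plp_site",
               own=(35, 98, 99, 126, 175, 200, 203, 226, 228, 229, 235, 363),
               other=(55, 57, 65, 263)),
        Region("folate_site", own=(121, 125, 127, 347), other=(57, 64)),
    ))


def write_region_config(regions: RegionSet) -> str:
    """Serialize a RegionSet to a flat INI-style text config."""
    cp = configparser.ConfigParser()
    for region in regions.regions:
        cp[region.name] = {
            "own": _nums_to_spec(region.own),
            "other": _nums_to_spec(region.other),
        }
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def read_region_config(text: str) -> RegionSet:
    """Parse the INI-style region config written by :func:`write_region_config`."""
    cp = configparser.ConfigParser()
    cp.read_string(text)
    regions = []
    for name in cp.sections():
        own = _spec_to_nums(cp[name].get("own", ""))
        other = _spec_to_nums(cp[name].get("other", ""))
        regions.append(Region(name, own=own, other=other))
    return RegionSet(regions=tuple(regions))


def _nums_to_spec(nums: tuple[int, ...]) -> str:
    if not nums:
        return ""
    parts = []
    start = prev = nums[0]
    for n in nums[1:]:
        if n == prev + 1:
            prev = n
            continue
        parts.append(f"{start}-{prev}" if prev > start else str(start))
        start = prev = n
    parts.append(f"{start}-{prev}" if prev > start else str(start))
    return ", ".join(parts)


def _spec_to_nums(spec: str) -> tuple[int, ...]:
    nums: list[int] = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            a, b = part.split("-")
            nums.extend(range(int(a), int(b) + 1))
        else:
            nums.append(int(part))
    return tuple(nums)
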