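"""Promoter-independent transcription scaffold: strands, annealing, extension walking.

An elongation complex (EC) is assembled on a synthetic nucleic-acid scaffold:
a 64-nt template DNA strand, its exact reverse complement (the non-template
strand), and a short RNA primer annealed to an internal template window.
RNA polymerase extends the primer 3' end along the template toward the
template 5' end, so each added nucleotide is the Watson-Crick complement of
the template residue immediately 5' (in template coordinates, one position
below) of the current register.

Coordinates are 1-based and inclusive on the template strand as printed
5'->3'.  ``EC_+n`` denotes an elongation complex carrying an n-nt RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "NucleicStrand",
    "ScaffoldSet",
    "ElongationComplex",
    "ScaffoldError",
    "NoMatchError",
    "AmbiguousMatchError",
    "TemplateExhaustedError",
    "reverse_complement",
    "find_annealing_window",
    "next_cognate_nucleotide",
    "extend_with_subset",
    "rnase_a_protection_products",
    "predict_hybrid_tm",
    "tk_scaffold",
    "TK_TEMPLATE",
    "TK_NON_TEMPLATE",
    "TK_RNA_PRIMER",
]

_DNA_ALPHABET = frozenset("ACGT")
_RNA_ALPHABET = frozenset("ACGU")

#: 64-nt template strand of the Thermococcus kodakarensis scaffold (5'->3').
TK_TEMPLATE = "ACCAGCAGGCCGATTGGGATGGGTATTCCCTCCTGCCTCTCGATGGCTGTAAGTATCCTATAGG"
#: 64-nt non-template strand, the exact reverse complement of the template.
TK_NON_TEMPLATE = "CCTATAGGATACTTACAGCCATCGAGAGGCAGGAGGGAATACCCATCCCAATCGGCCTGCTGGT"
#: 9-nt RNA primer annealed to template positions 36-44.
TK_RNA_PRIMER = "AUCGAGAGG"

_NTP_FOR_BASE = {"A": "ATP", "C": "CTP", "G": "GTP", "U": "UTP"}
_BASE_FOR_NTP = {v: k for k, v in _NTP_FOR_BASE.items()}


class ScaffoldError(ValueError):
    """Base class for scaffold-level sequence errors."""


class NoMatchError(ScaffoldError):
    """The reverse complement of the RNA does not occur in the template."""


class AmbiguousMatchError(ScaffoldError):
    """The annealing site occurs more than once; scaffold identity is not unique."""


class TemplateExhaustedError(ScaffoldError):
    """The RNA 3' end has reached template position 1; no further extension."""


@dataclass(frozen=True)
class NucleicStrand:
    """A single nucleic-acid strand, stored 5'->3'.

    Parameters
    ----------
    sequence :
        Residues over ``{A,C,G,T}`` (DNA) or ``{A,C,G,U}`` (RNA); upper-cased
        on construction.
    alphabet :
        ``"DNA"`` or ``"RNA"``.
    name :
        Free-text label carried through I/O.
    """

    sequence: str
    alphabet: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.alphabet not in ("DNA", "RNA"):
            raise ScaffoldError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")
        if len(self.sequence) < 1:
            raise ScaffoldError("strand must contain at least one residue")
        allowed = _DNA_ALPHABET if self.alphabet == "DNA" else _RNA_ALPHABET
        bad = set(self.sequence) - allowed
        if bad:
            raise ScaffoldError(
                f"invalid {self.alphabet} residues {sorted(bad)} in {self.name or 'strand'}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(strand: NucleicStrand, out_alphabet: str = "DNA") -> NucleicStrand:
    """Watson-Crick reverse complement, transliterating T<->U per *out_alphabet*."""
    if out_alphabet not in ("DNA", "RNA"):
        raise ScaffoldError(f"out_alphabet must be DNA or RNA, got {out_alphabet!r}")
    seq = Seq(strand.sequence)
    rc = str(seq.reverse_complement_rna() if out_alphabet == "RNA" else seq.reverse_complement())
    return NucleicStrand(rc, out_alphabet, name=f"revcomp({strand.name})" if strand.name else "")


def find_annealing_window(template: NucleicStrand, rna: NucleicStrand) -> tuple[int, int]:
    """Locate the unique template window whose reverse complement equals *rna*.

    Returns 1-based inclusive ``(start, end)`` coordinates on the template as
    printed 5'->3'.  Raises :class:`NoMatchError` if absent and
    :class:`AmbiguousMatchError` if the site occurs more than once.
    """
    if template.alphabet != "DNA":
        raise ScaffoldError("template must be DNA")
    if rna.alphabet != "RNA":
        raise ScaffoldError("primer must be RNA")
    probe = reverse_complement(rna, "DNA").sequence
    n = template.sequence.count(probe)
    if n == 0:
        raise NoMatchError(f"reverse complement {probe} not found in template")
    if n > 1:
        raise AmbiguousMatchError(f"annealing site {probe} occurs {n} times in template")
    start = template.sequence.index(probe) + 1
    return start, start + len(probe) - 1


@dataclass(frozen=True)
class ScaffoldSet:
    """Template, non-template and RNA strands plus annealing coordinates.

    Invariants enforced on construction: the non-template strand is the exact
    reverse complement of the template, and the RNA 3'-terminal residues match
    the reverse complement (DNA->RNA) of the annealing window.
    """

    template: NucleicStrand
    non_template: NucleicStrand
    rna: NucleicStrand
    anneal_start: int
    anneal_end: int

    def __post_init__(self) -> None:
        if reverse_complement(self.template, "DNA").sequence != self.non_template.sequence:
            raise ScaffoldError("non-template strand is not the reverse complement of the template")
        w = self.anneal_end - self.anneal_start + 1
        if w != min(len(self.rna), w):
            raise ScaffoldError("annealing window wider than the RNA")
        window = NucleicStrand(
            self.template.sequence[self.anneal_start - 1 : self.anneal_end], "DNA"
        )
        expect = reverse_complement(window, "RNA").sequence
        if self.rna.sequence[-w:] != expect:
            raise ScaffoldError(
                f"RNA 3' end {self.rna.sequence[-w:]} does not pair with template window "
                f"{self.anneal_start}-{self.anneal_end} (expected {expect})"
            )

    @classmethod
    def from_strands(
        cls, template: NucleicStrand, non_template: NucleicStrand, rna: NucleicStrand
    ) -> "ScaffoldSet":
        start, end = find_annealing_window(template, rna)
        return cls(template, non_template, rna, start, end)


def tk_scaffold() -> ScaffoldSet:
    """The bundled 64-nt *T. kodakarensis* scaffold with its 9-nt RNA primer."""
    return ScaffoldSet.from_strands(
        NucleicStrand(TK_TEMPLATE, "DNA", "template"),
        NucleicStrand(TK_NON_TEMPLATE, "DNA", "non-template"),
        NucleicStrand(TK_RNA_PRIMER, "RNA", "primer"),
    )


@dataclass(frozen=True)
class ElongationComplex:
    """An EC identified by its scaffold and current RNA.

    The *template register* is the 1-based template coordinate paired with the
    RNA 3' end; for the bundled scaffold the 9-mer primer sits at registers
    36-44, so ``register = anneal_start - (len(rna) - primer_len)``.
    """

    scaffold: ScaffoldSet
    rna: NucleicStrand
    primer_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.primer_length == 0:
            object.__setattr__(self, "primer_length", len(self.scaffold.rna))
        reg = self.template_register
        if reg < 1:
            raise ScaffoldError("RNA extends past the template 5' end")
        covered = self.scaffold.template.sequence[reg - 1 : self.scaffold.anneal_end]
        expect = reverse_complement(NucleicStrand(covered, "DNA"), "RNA").sequence
        if self.rna.sequence[-len(expect):] != expect:
            raise ScaffoldError("RNA does not pair with the template segment it covers")

    @property
    def rna_length(self) -> int:
        return len(self.rna)

    @property
    def template_register(self) -> int:
        return self.scaffold.anneal_start - (self.rna_length - self.primer_length)

    @classmethod
    def assemble(cls, scaffold: ScaffoldSet) -> "ElongationComplex":
        """The freshly assembled EC carrying the unextended primer (EC_+9 here)."""
        return cls(scaffold, scaffold.rna)


def next_cognate_nucleotide(ec: ElongationComplex) -> str:
    """NTP templated at the next position: complement of the residue one
    coordinate 5' (register - 1) of the RNA 3' end.

    Raises :class:`TemplateExhaustedError` at register 1.
    """
    reg = ec.template_register
    if reg <= 1:
        raise TemplateExhaustedError("RNA 3' end is at template position 1")
    base = ec.scaffold.template.sequence[reg - 2]
    return _NTP_FOR_BASE[str(Seq(base).complement_rna())]


def _extend_once(ec: ElongationComplex) -> ElongationComplex:
    ntp = next_cognate_nucleotide(ec)
    new_rna = NucleicStrand(ec.rna.sequence + _BASE_FOR_NTP[ntp], "RNA", ec.rna.name)
    return replace(ec, rna=new_rna)


def extend_with_subset(ec: ElongationComplex, allowed: set[str]) -> ElongationComplex:
    """Walk the template, appending cognate nucleotides while they are in *allowed*.

    Stops at the first cognate position requiring an NTP outside *allowed* or
    when the template is exhausted; an empty set returns the input unchanged.
    Models single-round extension with a restricted NTP pool (e.g. ATP+GTP
    extends the 10-mer to the 19-mer, stalling where UTP would be required).
    """
    bad = set(allowed) - set(_BASE_FOR_NTP)
    if bad:
        raise ScaffoldError(f"unknown NTPs {sorted(bad)}")
    while True:
        try:
            ntp = next_cognate_nucleotide(ec)
        except TemplateExhaustedError:
            return ec
        if ntp not in allowed:
            return ec
        ec = _extend_once(ec)


def rnase_a_protection_products(rna: NucleicStrand) -> tuple[list[str], str]:
    """Digest an RNA with RNase A: cleave 3' of every pyrimidine (C or U)
    except the 3'-terminal residue.

    Returns ``(fragments, labeled_fragment)`` where *fragments* are ordered
    5'->3' and *labeled_fragment* contains the 3' end — the fragment carrying
    an alpha-32P label incorporated at the 3'-most phosphodiester.  For the
    released 10-mer ``AUCGAGAGGC`` the labeled product is the 7-mer
    ``GAGAGGC`` that the protection assay scores against the intact 10-mer.
    """
    if rna.alphabet != "RNA":
        raise ScaffoldError("RNase A digestion operates on RNA")
    seq = rna.sequence
    if len(seq) < 2:
        raise ScaffoldError("need at least 2 residues to digest")
    fragments: list[str] = []
    start = 0
    for i, base in enumerate(seq[:-1]):  # 3'-terminal residue never yields a cut
        if base in "CU":
            fragments.append(seq[start : i + 1])
            start = i + 1
    fragments.append(seq[start:])
    return fragments, fragments[-1]


def predict_hybrid_tm(
    rna: NucleicStrand,
    dna_window: NucleicStrand,
    monovalent_salt_mM: float = 40.0,
    strand_nM: float = 250.0,
) -> float:
    """Nearest-neighbor melting temperature (deg C) of an RNA:DNA hybrid.

    Uses the Sugimoto RNA/DNA hybrid parameter set with a logarithmic
    monovalent-salt correction; the duplex Tm is computed from the RNA strand,
    so swapping the argument roles leaves the result unchanged.  Strands must
    be equal-length exact complements.
    """
    a, b = rna, dna_window
    if a.alphabet == "DNA" and b.alphabet == "RNA":
        a, b = b, a
    if a.alphabet != "RNA" or b.alphabet != "DNA":
        raise ScaffoldError("hybrid Tm needs one RNA and one DNA strand")
    if len(a) != len(b):
        raise ScaffoldError("hybrid strands must be equal length")
    if reverse_complement(b, "RNA").sequence != a.sequence:
        raise ScaffoldError("strands are not complementary")
    return float(
        _mt.Tm_NN(
            a.sequence,
            nn_table=_mt.R_DNA_NN1,
            Na=monovalent_salt_mM,
            dnac1=strand_nM,
            dnac2=strand_nM,
            saltcorr=5,
        )
    )
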