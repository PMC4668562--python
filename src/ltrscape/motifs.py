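"""Bundled peptide motifs and lineage reference RT sequences.

The package ships one integrase (INT) and one reverse-transcriptase (RT)
core peptide per autonomous superfamily, plus one reference RT nucleotide
sequence per named lineage.  Both files are synthetic stand-ins written
for this package (see the ``_synthetic`` suffix): the peptides mimic the
conserved cores that distinguish the domains, and the lineage references
are mutually diverged sequences carrying the superfamily's RT core, which
is all that domain-order classification and nearest-reference lineage
assignment require.  Both files are plain inputs and can be replaced by
curated sequences without code changes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

_DATA = resources.files("ltrscape") / "data"

COPIA_LINEAGES = ["Ale", "Ivana", "Bianca", "Angela", "TAR", "Maximus"]
GYPSY_LINEAGES = ["Tekay", "Galadriel", "CRM", "Reina", "Athila", "Ogre", "Tat"]

_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """One random in-frame nucleotide realization of a peptide."""
    return "".join(
        _AA_TO_CODONS[aa][int(rng.integers(0, len(_AA_TO_CODONS[aa])))] for aa in peptide
    )


def superfamily_motifs(path: str | Path | None = None) -> dict[str, dict[str, str]]:
    """{superfamily: {domain: peptide}} from the bundled (or given) TSV."""
    if path is None:
        text = (_DATA / "motifs_synthetic.tsv").read_text()
    else:
        text = Path(path).read_text()
    out: dict[str, dict[str, str]] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        sf, domain, pep = line.split("\t")
        out.setdefault(sf, {})[domain] = pep
    return out


def lineage_references(path: str | Path | None = None) -> list[tuple[str, str, str]]:
    """[(lineage, superfamily, nt_sequence)] reference RT set.

    Bundled file: one synthetic reference per lineage, headers formatted
    ``>lineage superfamily``.
    """
    if path is None:
        text = (_DATA / "lineage_rt_refs_synthetic.fasta").read_text()
    else:
        text = Path(path).read_text()
    refs: list[tuple[str, str, str]] = []
    name = sf = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                refs.append((name, sf, "".join(chunks)))
            fields = line[1:].split()
            name, sf = fields[0], fields[1]
            chunks = []
        else:
            chunks.append(line.strip().upper())
    if name is not None:
        refs.append((name, sf, "".join(chunks)))
    return refs
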