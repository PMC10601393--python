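"""Reading and writing the Genepop genotype interchange format.

Genepop files are plain text: a free-form title line, one locus name per
line (or a single comma-separated line), then population blocks each
introduced by a line reading ``pop`` (any casing). Individual records are
``id , a1a2 a1a2 ...`` with fixed-width allele codes — three digits per
allele by default (``020015`` = alleles 20 and 15), two-digit files are
auto-detected. Code 0 (``000`` / ``0000``/``000000``) marks a missing
allele. No package in the installed stack parses this format, so the
parser lives here.
"""
from __future__ import annotations

import numpy as np

from .containers import MISSING, GenotypeDataset, LocusSpec

__all__ = ["read_genepop", "write_genepop", "GenepopError"]

_POP_SEPARATORS = {"pop"}


class GenepopError(ValueError):
    """Malformed Genepop document."""


def _is_pop_line(line: str) -> bool:
    return line.strip().lower() in _POP_SEPARATORS


def _parse_alleles(token: str, lineno: int) -> tuple[int, int]:
    if len(token) in (4, 6) and token.isdigit():
        w = len(token) // 2
        a1, a2 = int(token[:w]), int(token[w:])
        return (a1 if a1 != 0 else MISSING, a2 if a2 != 0 else MISSING)
    raise GenepopError(
        f"line {lineno}: allele code {token!r} is not a 4- or 6-digit genotype"
    )


def read_genepop(
    text: str, locus_specs: list[LocusSpec] | None = None
) -> GenotypeDataset:
    """Parse a Genepop document into a :class:`GenotypeDataset`.

    Populations appear in file order and are labelled by the id of their
    last individual (the Genepop convention) or ``pop1..popN`` when ids
    are uninformative duplicates. ``locus_specs`` optionally overrides the
    default allele-window metadata attached to each parsed locus.
    """
    lines = text.splitlines()
    if not lines:
        raise GenepopError("empty document")
    # locate locus list: lines 2.. until first pop separator
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not _is_pop_line(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if not locus_names:
        raise GenepopError("no locus names before the first 'pop' line")
    if i == len(lines):
        raise GenepopError("no 'pop' separator found")

    pops: list[list[tuple[str, list[tuple[int, int]]]]] = []
    while i < len(lines):
        if _is_pop_line(lines[i]):
            pops.append([])
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," in line:
            ind_id, rest = line.split(",", 1)
        else:
            # tolerate missing comma: first token is the id
            parts = line.split(None, 1)
            ind_id, rest = parts[0], parts[1] if len(parts) > 1 else ""
        tokens = rest.split()
        if len(tokens) != len(locus_names):
            raise GenepopError(
                f"line {i + 1}: individual {ind_id.strip()!r} has {len(tokens)} "
                f"genotypes for {len(locus_names)} loci"
            )
        genos = [_parse_alleles(tok, i + 1) for tok in tokens]
        pops[-1].append((ind_id.strip(), genos))
        i += 1
    if any(len(p) == 0 for p in pops):
        raise GenepopError("empty population block")

    if locus_specs is not None:
        if len(locus_specs) != len(locus_names):
            raise GenepopError("locus_specs length does not match file locus count")
        loci = locus_specs
    else:
        # infer a generous allele window from the observed range per locus
        loci = []
        for l, name in enumerate(locus_names):
            observed = [
                a
                for block in pops
                for _, genos in block
                for a in genos[l]
                if a != MISSING
            ]
            if observed:
                center = int(round(float(np.mean(observed))))
                span = max(max(observed) - min(observed) + 1, 40)
                center = max(center, span // 2 + 1)
            else:
                center, span = 20, 40
            loci.append(LocusSpec(name, ancestral_size=center, allowed_states=span))

    pop_sizes = np.array([len(p) for p in pops], dtype=np.int64)
    labels = []
    for k, block in enumerate(pops):
        last_id = block[-1][0]
        labels.append(last_id if last_id else f"pop{k + 1}")
    if len(set(labels)) != len(labels):
        labels = [f"pop{k + 1}" for k in range(len(pops))]
    genotypes = np.full((int(pop_sizes.sum()), len(loci), 2), MISSING, dtype=np.int16)
    ids = []
    row = 0
    for block in pops:
        for ind_id, genos in block:
            ids.append(ind_id)
            for l, (a1, a2) in enumerate(genos):
                genotypes[row, l, 0] = a1
                genotypes[row, l, 1] = a2
            row += 1
    return GenotypeDataset(
        populations=labels,
        pop_sizes=pop_sizes,
        loci=loci,
        genotypes=genotypes,
        individual_ids=ids,
    )


def write_genepop(ds: GenotypeDataset, title: str = "msatabc export") -> str:
    """Render a dataset as a Genepop document (3-digit allele codes).

    The title line doubles as the provenance header; allele sizes must fit
    in three digits.
    """
    if ds.genotypes.max() > 999:
        raise GenepopError("allele sizes exceed the 3-digit Genepop dialect")
    out = [title.replace("\n", " ")]
    out.extend(spec.name for spec in ds.loci)
    row = 0
    for p, size in enumerate(ds.pop_sizes):
        out.append("pop")
        for _ in range(size):
            ind = ds.individual_ids[row] if ds.individual_ids else f"ind{row + 1}"
            codes = []
            for l in range(ds.n_loci):
                a1, a2 = ds.genotypes[row, l]
                c1 = 0 if a1 == MISSING else int(a1)
                c2 = 0 if a2 == MISSING else int(a2)
                codes.append(f"{c1:03d}{c2:03d}")
            out.append(f"{ind} , " + " ".join(codes))
            row += 1
    return "\n".join(out) + "\n"
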