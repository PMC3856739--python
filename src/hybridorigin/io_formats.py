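"""Reading and writing GENEPOP genotype files and behavioral trial tables.

The GENEPOP dialect accepted here: a title line, one or more locus-name
lines (single name per line, or several comma-separated), populations
delimited by a line reading ``Pop`` (any case), and individual lines of the
form ``id , a1a2 a1a2 ...`` where each genotype token concatenates two
fixed-width (2- or 3-digit) allele codes. ``00``/``000`` encodes a missing
gene copy; a genotype is missing only when both copies are 0.

GENEPOP has no field for population names, so labels survive a round trip
through the widely used id convention ``<label>_<individual>``: when every
id in a population block shares such a prefix the prefix becomes the label,
otherwise blocks are named ``pop1``, ``pop2``, ... in file order. The
synthetic generator always emits prefixed ids, so its tables round-trip
exactly.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable, PreferenceTrial, PreferenceTrialSet

TRIAL_COLUMNS = ["female_id", "female_pop", "combination", "m", "n"]


class GenepopParseError(ValueError):
    """Raised when a GENEPOP file is malformed."""


def _is_pop_line(line: str) -> bool:
    return line.strip().lower() == "pop"


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a GENEPOP file into a :class:`GenotypeTable`.

    Population labels are ``pop1``, ``pop2``, ... in file order unless every
    individual id in a population block shares a common label prefix of the
    form ``label_...``, in which case that prefix is used. Both 2- and
    3-digit allele encodings are accepted (the width is inferred from the
    first genotype token and must be consistent).
    """
    text = Path(path).read_text()
    lines = [ln.rstrip("\n") for ln in text.splitlines()]
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 3:
        raise GenepopParseError("file too short to be a GENEPOP file")

    # locus names: everything between the title line and the first Pop line
    loci: list[str] = []
    body_start = None
    for i, ln in enumerate(lines[1:], start=1):
        if _is_pop_line(ln):
            body_start = i
            break
        loci.extend(name.strip() for name in ln.split(",") if name.strip())
    if body_start is None:
        raise GenepopParseError("no 'Pop' line found")
    if not loci:
        raise GenepopParseError("no locus names before the first 'Pop' line")

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_index = 0
    width: int | None = None

    for lineno, ln in enumerate(lines[body_start:], start=body_start + 1):
        if _is_pop_line(ln):
            pop_index += 1
            continue
        if "," not in ln:
            raise GenepopParseError(
                f"line {lineno}: expected 'id , genotypes' (no comma found)"
            )
        ind_id, geno_part = ln.split(",", 1)
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {lineno}: individual {ind_id!r} has {len(tokens)} "
                f"genotypes but {len(loci)} loci are declared"
            )
        row: list[tuple[int, int]] = []
        for tok in tokens:
            if width is None:
                if len(tok) == 4:
                    width = 2
                elif len(tok) == 6:
                    width = 3
                else:
                    raise GenepopParseError(
                        f"line {lineno}: genotype token {tok!r} has length "
                        f"{len(tok)}; expected 4 (2-digit) or 6 (3-digit)"
                    )
            if len(tok) != 2 * width or not tok.isdigit():
                raise GenepopParseError(
                    f"line {lineno}: genotype token {tok!r} does not match "
                    f"the {width}-digit encoding"
                )
            a1, a2 = int(tok[:width]), int(tok[width:])
            if (a1 == 0) != (a2 == 0):
                raise GenepopParseError(
                    f"line {lineno}: half-missing genotype {tok!r} "
                    "(exactly one allele code is 0)"
                )
            row.append((a1, a2))
        individuals.append(ind_id)
        populations.append(f"pop{pop_index + 1}")
        rows.append(row)

    if not rows:
        raise GenepopParseError("no individuals found")

    # prefer the common 'label_' id prefix of each block as its label
    pop_labels = populations[:]
    for pop in dict.fromkeys(populations):
        idx = [i for i, p in enumerate(populations) if p == pop]
        prefixes = {
            individuals[i].split("_")[0] for i in idx if "_" in individuals[i]
        }
        if len(prefixes) == 1 and all("_" in individuals[i] for i in idx):
            label = prefixes.pop()
            for i in idx:
                pop_labels[i] = label
    if len(set(pop_labels)) != len(set(populations)):
        pop_labels = populations  # prefix collision: fall back to pop1, pop2, ...

    genotypes = np.array(rows, dtype=np.int64)
    return GenotypeTable(individuals, pop_labels, loci, genotypes)


def write_genepop(
    table: GenotypeTable, path: str | Path, title: str = "hybridorigin export"
) -> None:
    """Write a table in the 3-digit GENEPOP dialect (missing genotype = 000000)."""
    if table.n_individuals == 0:
        raise ValueError("cannot write a GENEPOP file with no individuals")
    if table.genotypes.max(initial=0) > 999:
        raise ValueError("allele codes above 999 cannot use the 3-digit encoding")
    buf = io.StringIO()
    buf.write(title + "\n")
    for locus in table.loci:
        buf.write(locus + "\n")
    for pop in table.population_names:
        buf.write("Pop\n")
        for i in table.population_indices(pop):
            ind = table.individuals[i]
            tokens = [
                f"{a1:03d}{a2:03d}" for a1, a2 in table.genotypes[i]
            ]
            buf.write(f"{ind} , " + " ".join(tokens) + "\n")
    Path(path).write_text(buf.getvalue())


def read_trials(path: str | Path) -> PreferenceTrialSet:
    """Read a behavioral trial table (CSV with header female_id,female_pop,combination,m,n)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    trials = [
        PreferenceTrial(
            female_id=str(r.female_id),
            female_pop=str(r.female_pop),
            combination=str(r.combination),
            m=float(r.m),
            n=float(r.n),
        )
        for r in df.itertuples()
    ]
    return PreferenceTrialSet(trials)


def write_trials(trial_set: PreferenceTrialSet, path: str | Path) -> None:
    # times are written with full repr precision so a round trip is exact
    lines = [",".join(TRIAL_COLUMNS)]
    for t in trial_set.trials:
        lines.append(
            f"{t.female_id},{t.female_pop},{t.combination},{t.m!r},{t.n!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
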