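"""Gene signatures and directional pathway definitions.

Two kinds of gene sets drive the pipeline:

* :class:`GeneSignature` — a plain named gene set, e.g. the 160-gene
  T cell-inflamed signature used to stratify tumors, or the packaged
  12-gene p38 activation signature.
* :class:`PathwayDefinition` — an upstream regulator (e.g. MAPK14,
  CTNNB1) with its downstream target genes, each annotated with the
  expected direction of regulation (``up`` or ``down``).  Directions
  let scoring weight each target by the sign the pathway is expected
  to impose on it.

Both are read from GMT files.  Plain signatures use the standard GMT
layout (name, description, genes...).  Pathway definitions use a
directional GMT dialect in which each gene token may carry a ``|up``
or ``|down`` suffix; an unsuffixed token defaults to ``up``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

VALID_DIRECTIONS = ("up", "down")


class GmtParseError(ValueError):
    """Raised when a GMT (or directional GMT) file cannot be parsed."""


def _check_symbol(sym: str, context: str) -> None:
    if not sym or any(ch.isspace() for ch in sym):
        raise ValueError(f"{context}: invalid gene symbol {sym!r}")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with unique, ordered gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        for g in self.genes:
            _check_symbol(g, f"signature {self.name!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class PathwayDefinition:
    """An upstream regulator with signed downstream targets.

    ``targets`` is an ordered tuple of ``(gene_symbol, direction)``
    pairs with ``direction`` one of ``"up"`` / ``"down"``.
    """

    regulator: str
    targets: tuple[tuple[str, str], ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.regulator:
            raise ValueError("pathway regulator must be non-empty")
        if not self.targets:
            raise ValueError(f"pathway {self.regulator!r} has no targets")
        seen: set[str] = set()
        for gene, direction in self.targets:
            _check_symbol(gene, f"pathway {self.regulator!r}")
            if direction not in VALID_DIRECTIONS:
                raise ValueError(
                    f"pathway {self.regulator!r}: direction {direction!r} "
                    f"not in {VALID_DIRECTIONS}"
                )
            if gene in seen:
                raise ValueError(
                    f"pathway {self.regulator!r}: duplicate target {gene!r}"
                )
            seen.add(gene)
        object.__setattr__(self, "targets", tuple(map(tuple, self.targets)))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.targets)

    def signs(self) -> dict[str, int]:
        """Map target gene -> +1 (up) or -1 (down)."""
        return {g: (1 if d == "up" else -1) for g, d in self.targets}

    def __len__(self) -> int:
        return len(self.targets)


def _gmt_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    nonempty = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not nonempty:
        raise GmtParseError(f"{path}: empty GMT file")
    for lineno, ln in nonempty:
        fields = ln.rstrip("\r\n").split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"{path}:{lineno}: expected >=3 tab-separated fields, "
                f"got {len(fields)}"
            )
        yield lineno, fields


def load_gmt(path: str | Path) -> list[GeneSignature]:
    """Load plain gene signatures from a standard GMT file.

    Duplicate gene tokens within one line are collapsed (first
    occurrence kept) with a logged warning.
    """
    out: list[GeneSignature] = []
    for lineno, fields in _gmt_lines(path):
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        uniq = list(dict.fromkeys(genes))
        if len(uniq) != len(genes):
            logger.warning(
                "%s:%d: signature %s has duplicate gene tokens; collapsed "
                "%d -> %d", path, lineno, name, len(genes), len(uniq)
            )
        if not uniq:
            raise GmtParseError(f"{path}:{lineno}: signature {name!r} has no genes")
        out.append(GeneSignature(name=name, genes=tuple(uniq)))
    return out


def write_gmt(signatures: Sequence[GeneSignature], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([sig.name, description, *sig.genes]) for sig in signatures
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_directional_token(tok: str, context: str) -> tuple[str, str]:
    if "|" in tok:
        gene, _, suffix = tok.partition("|")
        if suffix not in VALID_DIRECTIONS:
            raise GmtParseError(
                f"{context}: unknown direction suffix {suffix!r} in token {tok!r}"
            )
        return gene, suffix
    return tok, "up"


def load_directional_gmt(path: str | Path) -> list[PathwayDefinition]:
    """Load signed pathway definitions from the directional GMT dialect.

    Each gene token may be ``GENE``, ``GENE|up`` or ``GENE|down``; a
    bare token defaults to ``up``.  The GMT description field is kept
    as the definition's provenance note.
    """
    out: list[PathwayDefinition] = []
    for lineno, fields in _gmt_lines(path):
        name, desc, *tokens = fields
        tokens = [t for t in tokens if t]
        targets: list[tuple[str, str]] = []
        seen: set[str] = set()
        for tok in tokens:
            gene, direction = _parse_directional_token(tok, f"{path}:{lineno}")
            if gene in seen:
                logger.warning(
                    "%s:%d: pathway %s duplicate target %s dropped",
                    path, lineno, name, gene,
                )
                continue
            seen.add(gene)
            targets.append((gene, direction))
        if not targets:
            raise GmtParseError(f"{path}:{lineno}: pathway {name!r} has no targets")
        out.append(PathwayDefinition(regulator=name, targets=tuple(targets),
                                     source=desc))
    return out


def write_directional_gmt(pathways: Sequence[PathwayDefinition],
                          path: str | Path) -> None:
    lines = []
    for pw in pathways:
        toks = [f"{g}|{d}" for g, d in pw.targets]
        lines.append("\t".join([pw.regulator, pw.source or "na", *toks]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


#: The 12-gene p38 pathway activation signature derived in HPV-negative
#: HNSCC and applied pan-cancer.  VEGFA is the downstream target shared
#: with the other nominated immune-exclusion pathways.
P38_SIGNATURE_GENES: tuple[str, ...] = (
    "ARG2", "CD55", "CYP4F3", "FST", "GCLC", "IL1A",
    "MIF", "PLA2G4A", "PTGS2", "S100A12", "SLC6A2", "VEGFA",
)


def builtin_p38_signature() -> GeneSignature:
    """The packaged 12-gene p38 pathway activation signature."""
    return GeneSignature(name="P38_ACTIVATION_12", genes=P38_SIGNATURE_GENES)
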