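"""Gene signatures: named up/down gene lists with file I/O.

Signatures originate from differential-expression contrasts; the selection
convention used throughout is log2 fold change > 1 for up-regulated genes and
log2 fold change < 0 for down-regulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

UP_LOG2FC_CUT = 1.0
DOWN_LOG2FC_CUT = 0.0


@dataclass
class GeneSignature:
    """Named gene signature with up- and down-regulated member lists."""

    name: str
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: genes in both up and down lists: "
                f"{sorted(overlap)[:5]}"
            )
        if not self.up_genes and not self.down_genes:
            raise ValueError(f"signature {self.name!r} is empty")

    @classmethod
    def from_de_table(cls, name, table, up_cut=UP_LOG2FC_CUT, down_cut=DOWN_LOG2FC_CUT):
        """Build a signature from a DE result table (log2fc column, gene index)."""
        up = table.index[table["log2fc"] > up_cut].tolist()
        down = table.index[table["log2fc"] < down_cut].tolist()
        return cls(name=name, up_genes=up, down_genes=down)


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a signature file.

    Accepts one gene per line (all treated as up-regulated) or two
    tab-separated columns ``gene<TAB>direction`` with direction in
    {up, down}.
    """
    path = Path(path)
    up: list[str] = []
    down: list[str] = []
    for i, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            up.append(parts[0])
        elif len(parts) == 2:
            gene, direction = parts[0], parts[1].lower()
            if direction == "up":
                up.append(gene)
            elif direction == "down":
                down.append(gene)
            else:
                raise ValueError(f"{path}:{i}: unknown direction {parts[1]!r}")
        else:
            raise ValueError(f"{path}:{i}: expected 1 or 2 columns, got {len(parts)}")
    return GeneSignature(name=name or path.stem, up_genes=up, down_genes=down)


def write_signature(signature: GeneSignature, path: str | Path) -> None:
    path = Path(path)
    lines = [f"{g}\tup" for g in signature.up_genes]
    lines += [f"{g}\tdown" for g in signature.down_genes]
    path.write_text("\n".join(lines) + "\n")
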