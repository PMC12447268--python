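"""Packaged gene-signature sets and loading helpers."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List

import yaml


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty marker gene list."""

    name: str
    genes: tuple

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", tuple(self.genes))


def load_signatures(path=None) -> Dict[str, GeneSignature]:
    """Load signatures from a YAML mapping name -> gene list.

    Defaults to the signature sets shipped with the package.
    """
    if path is None:
        text = resources.files("clonaltrack.data").joinpath(
            "signatures.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: GeneSignature(name, tuple(genes)) for name, genes in raw.items()}


def default_signatures() -> Dict[str, GeneSignature]:
    return load_signatures(None)


def all_signature_genes(signatures: Dict[str, GeneSignature]) -> List[str]:
    """Deduplicated union of all signature genes, in first-seen order."""
    seen = []
    for sig in signatures.values():
        for g in sig.genes:
            if g not in seen:
                seen.append(g)
    return seen
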