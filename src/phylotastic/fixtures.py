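"""Synthetic data generators: random trees, ultrametric chronograms,
taxonomy tables and name-corruption utilities, plus the packaged small
mammal example tree.

These are first-class, seed-deterministic generators (every function is a
pure function of its spec), intended to exercise the toolkit without any
downloaded data. The branching model is a simple equal-rates (Yule-like)
split process — structurally valid phylogenies, not a realistic
diversification model.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np

from .errors import PhylotasticError
from .tnrs import TaxonomyTable
from .trees import Node, Tree, parse_newick

__all__ = ["GeneratorSpec", "random_tree", "random_ultrametric_tree",
           "random_taxonomy", "random_binomials", "corrupt_name",
           "mammal_fixture", "MAMMAL_NEWICK", "MAMMAL_TAXONOMY_CSV"]


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic generators; ``seed`` fully determines
    the output."""
    n_tips: int = 16
    model: str = "equal-rates"
    age_root: float = 100.0
    seed: int = 0
    label_pool: Optional[Sequence[str]] = None
    polytomy_rate: float = 0.0   # probability a split yields 3 children
    with_lengths: bool = True

    def __post_init__(self):
        if self.n_tips < 1:
            raise ValueError("n_tips must be >= 1")


def _labels(spec: GeneratorSpec) -> list[str]:
    if spec.label_pool is not None:
        if len(spec.label_pool) < spec.n_tips:
            raise ValueError("label pool smaller than n_tips")
        return list(spec.label_pool[:spec.n_tips])
    return [f"t{i + 1}" for i in range(spec.n_tips)]


def random_tree(spec: GeneratorSpec) -> Tree:
    """Random rooted tree grown by equal-rates splitting of a uniformly
    chosen tip. Binary by default; ``polytomy_rate`` makes some splits
    ternary. Branch lengths (when ``with_lengths``) are uniform on
    [0.1, 2.0)."""
    rng = np.random.default_rng(spec.seed)
    root = Node()
    tips = [root]
    while len(tips) < spec.n_tips:
        idx = int(rng.integers(len(tips)))
        node = tips[idx]
        n_children = 3 if (spec.polytomy_rate > 0
                           and rng.random() < spec.polytomy_rate
                           and len(tips) + 2 <= spec.n_tips) else 2
        children = [node.add_child(Node()) for _ in range(n_children)]
        tips[idx] = children[0]
        tips.extend(children[1:])
    labels = _labels(spec)
    order = rng.permutation(spec.n_tips)
    for tip, k in zip(tips, order):
        tip.label = labels[k]
    if spec.with_lengths:
        tree = Tree(root, name=f"random-{spec.seed}")
        for node in tree.preorder():
            if not node.is_root:
                node.branch_length = float(np.round(rng.uniform(0.1, 2.0), 6))
        return tree
    return Tree(root, name=f"random-{spec.seed}")


def random_ultrametric_tree(spec: GeneratorSpec) -> Tree:
    """Random chronogram: equal-rates topology with node ages drawn
    root-ward (each internal node's age is a uniform fraction of its
    parent's), tips at age 0, root at ``age_root``. Every root-to-tip path
    length equals ``age_root`` exactly (up to float rounding)."""
    topo_spec = GeneratorSpec(n_tips=spec.n_tips, seed=spec.seed,
                              label_pool=spec.label_pool,
                              polytomy_rate=spec.polytomy_rate,
                              with_lengths=False)
    tree = random_tree(topo_spec)
    rng = np.random.default_rng(spec.seed + 1)
    tree.root.age = float(spec.age_root)
    for node in tree.preorder():
        if node.is_root:
            continue
        if node.is_tip:
            node.age = 0.0
        else:
            node.age = node.parent.age * float(rng.uniform(0.3, 0.9))
        node.branch_length = node.parent.age - node.age
    tree.name = f"chronogram-{spec.seed}"
    return tree


_SYL = ["ba", "ce", "do", "fu", "gi", "lo", "ma", "ne", "pi", "ra",
        "su", "ta", "vu", "xe", "zo"]


def random_binomials(n: int, seed: int = 0) -> list[str]:
    """``n`` unique synthetic Latin-binomial-shaped names ("Genus species")."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen = set()
    while len(out) < n:
        genus = "".join(_SYL[i] for i in
                        rng.integers(len(_SYL), size=3)).capitalize()
        epithet = "".join(_SYL[i] for i in rng.integers(len(_SYL), size=3))
        name = f"{genus} {epithet}"
        if name not in seen:
            seen.add(name)
            out.append(name)
    return out


def random_taxonomy(spec: GeneratorSpec,
                    synonym_fraction: float = 0.3,
                    tip_labels: Optional[Sequence[str]] = None
                    ) -> TaxonomyTable:
    """MSW3-like taxonomy table with Order/Family/Genus/Species columns and a
    free-text Synonyms column embedding ``<i>...</i>``-tagged alternates for
    ``synonym_fraction`` of the rows.

    When ``tip_labels`` is given (e.g. a companion tree's tips, underscore
    form allowed), the accepted binomials are taken from it so the table and
    the tree agree.
    """
    rng = np.random.default_rng(spec.seed + 2)
    if tip_labels is not None:
        binomials = []
        for lb in tip_labels:
            parts = lb.replace("_", " ").split()
            binomials.append(" ".join(parts) if len(parts) > 1
                             else f"{parts[0]} sp")
    else:
        binomials = random_binomials(spec.n_tips, seed=spec.seed + 3)
    synonym_pool = random_binomials(2 * len(binomials), seed=spec.seed + 4)
    synonym_pool = [s for s in synonym_pool if s not in set(binomials)]
    rows = []
    for i, binom in enumerate(binomials):
        genus, *rest = binom.split()
        species = " ".join(rest)
        order = f"Order{1 + i % max(2, spec.n_tips // 6)}"
        family = f"Family{1 + i % max(2, spec.n_tips // 3)}"
        if rng.random() < synonym_fraction and synonym_pool:
            syn = synonym_pool[i % len(synonym_pool)]
            synonyms = f"considered distinct from <i>{syn}</i> by some authors"
        else:
            synonyms = ""
        rows.append({"Order": order, "Family": family, "Genus": genus,
                     "Species": species, "Author": f"Author, {1900 + i}",
                     "Synonyms": synonyms})
    import pandas as pd
    return TaxonomyTable(pd.DataFrame(rows), source_id=f"synthetic-{spec.seed}")


_ALPHABET = string.ascii_lowercase


def corrupt_name(name: str, n_edits: int, seed: int = 0) -> str:
    """Apply exactly ``n_edits`` single-character edits (substitution,
    insertion or deletion), deterministic per seed; the result is verified to
    be at edit distance exactly ``n_edits`` from the input."""
    if n_edits == 0:
        return name
    rng = np.random.default_rng(seed)
    for _ in range(200):  # retry: random edits can cancel each other
        out = name
        for _ in range(n_edits):
            op = rng.choice(["sub", "ins", "del"])
            pos = int(rng.integers(len(out))) if out else 0
            ch = _ALPHABET[int(rng.integers(26))]
            if op == "sub" and out:
                if out[pos] == ch:
                    ch = _ALPHABET[(_ALPHABET.index(ch) + 1) % 26]
                out = out[:pos] + ch + out[pos + 1:]
            elif op == "del" and len(out) > 1:
                out = out[:pos] + out[pos + 1:]
            else:
                out = out[:pos] + ch + out[pos:]
        if edlib.align(out, name, task="distance")["editDistance"] == n_edits:
            return out
    raise PhylotasticError(
        f"could not corrupt {name!r} to distance {n_edits}")


# ----------------------------------------------------------------------
# packaged mammal example
# ----------------------------------------------------------------------

MAMMAL_NEWICK = (
    "(((((((Homo_sapiens,Pan_troglodytes),Gorilla_gorilla)Hominidae,"
    "Pongo_pygmaeus)Hominoidea,Macaca_mulatta)Primates,"
    "(((Mus_musculus,Rattus_norvegicus)Muridae,Cavia_porcellus)Rodentia,"
    "Oryctolagus_cuniculus)Glires),"
    "((((Canis_lupus,Felis_catus)Carnivora,Equus_caballus),"
    "(Bos_taurus,Sus_scrofa)Artiodactyla)Laurasiatheria,"
    "(Loxodonta_africana,Trichechus_manatus)Afrotheria)),"
    "(Monodelphis_domestica,Ornithorhynchus_anatinus));"
)

MAMMAL_TAXONOMY_CSV = """\
Order,Family,Genus,Species,Author,Synonyms
Primates,Hominidae,Homo,sapiens,"Linnaeus, 1758",
Primates,Hominidae,Pan,troglodytes,"Blumenbach, 1775",includes <i>Simia troglodytes</i>
Primates,Hominidae,Gorilla,gorilla,"Savage, 1847",
Primates,Hominidae,Pongo,pygmaeus,"Linnaeus, 1760",
Primates,Cercopithecidae,Macaca,mulatta,"Zimmermann, 1780",
Rodentia,Muridae,Mus,musculus,"Linnaeus, 1758",includes <i>Mus domesticus</i>
Rodentia,Muridae,Rattus,norvegicus,"Berkenhout, 1769",
Rodentia,Caviidae,Cavia,porcellus,"Linnaeus, 1758",
Lagomorpha,Leporidae,Oryctolagus,cuniculus,"Linnaeus, 1758",
Carnivora,Canidae,Canis,lupus,"Linnaeus, 1758",
Carnivora,Felidae,Felis,catus,"Linnaeus, 1758",includes <i>Felis silvestris</i> in part
Perissodactyla,Equidae,Equus,caballus,"Linnaeus, 1758",
Artiodactyla,Bovidae,Bos,taurus,"Linnaeus, 1758",
Artiodactyla,Suidae,Sus,scrofa,"Linnaeus, 1758",
Proboscidea,Elephantidae,Loxodonta,africana,"Blumenbach, 1797",
Sirenia,Trichechidae,Trichechus,manatus,"Linnaeus, 1758",
Didelphimorphia,Didelphidae,Monodelphis,domestica,"Wagner, 1842",
Monotremata,Ornithorhynchidae,Ornithorhynchus,anatinus,"Shaw, 1799",
"""


def mammal_fixture() -> tuple[Tree, TaxonomyTable]:
    """The packaged 18-tip mammal tree and its matching taxonomy table.

    Homo_sapiens and Pan_troglodytes are sisters with Mus_musculus outside
    that clade, so pruning to the three reproduces the classic
    ``((Homo_sapiens,Pan_troglodytes),Mus_musculus);`` topology. Internal
    nodes carry family/order labels usable for taxonomic grafting.
    """
    tree = parse_newick(MAMMAL_NEWICK, name="mammals-demo")
    table = TaxonomyTable.from_csv_text(MAMMAL_TAXONOMY_CSV,
                                        source_id="mammal-demo-taxonomy")
    return tree, table
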