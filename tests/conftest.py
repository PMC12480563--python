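import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from hgtscan.tree_io import annotate_tree, load_taxonomy_map, parse_gene_tree


def build_annotated(newick: str, role_rows: dict[str, str], og_id: str = "OG1"):
    """role_rows: leaf -> 'query' | 'ingroup' | 'sister' | 'outgroup:Lineage'."""
    lines = ["seq_id\trole\tlineage"]
    for leaf, spec in role_rows.items():
        if ":" in spec:
            role, lineage = spec.split(":", 1)
        else:
            role, lineage = spec, ""
        lines.append(f"{leaf}\t{role}\t{lineage}")
    taxmap = load_taxonomy_map("\n".join(lines) + "\n")
    return annotate_tree(parse_gene_tree(newick), taxmap, og_id)


@pytest.fixture
def ancient_hgt_tree():
    """Query + sister nested beside three Stramenopila, two Alveolata
    deeper: the walk should call ancestral_hgt at the second clade."""
    return build_annotated(
        "(((q:1,s1:1)1.0:1,(o1:1,o2:1,o3:1)1.0:1)1.0:1,(x1:1,x2:1)1.0:1);",
        {
            "q": "query",
            "s1": "sister",
            "o1": "outgroup:Stramenopila",
            "o2": "outgroup:Stramenopila",
            "o3": "outgroup:Stramenopila",
            "x1": "outgroup:Alveolata",
            "x2": "outgroup:Alveolata",
        },
    )
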