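"""Publish an FDP tree with embedded MIAPPE metadata, then crawl it.

The FAIR Data Point exposes four linked levels (root, catalog, dataset,
distribution).  Embedding a MIAPPE investigation summary at the dataset
level lets a harvester decide which dataset is relevant — here, spotting
the phenotyping trials among three catalogs — without ever opening a
distribution.
"""

import tempfile

from phenofair.fdp import (
    FdpNode,
    build_fdp,
    crawl_fdp,
    embed_investigation,
    emit_tree,
    file_fetcher,
)
from phenofair.synth import FixtureSpec, generate_fixture
from phenofair.vocab import UriPolicy

fx = generate_fixture(FixtureSpec.small(seed=1))
policy = UriPolicy("https://fdp.example.org/id/")

root = FdpNode("fdp-root", "fdp_root", "Institute FAIR Data Point")
catalogs = [FdpNode(f"catalog-{t}", "catalog", f"{t.capitalize()} catalog",
                    theme=t, parent_id="fdp-root")
            for t in ("phenotypic", "genotypic", "genomic")]
dataset = FdpNode("dataset-cxe", "dataset", fx.investigation.title,
                  theme="phenotypic", parent_id="catalog-phenotypic")
dist = FdpNode("dist-sparql", "distribution", "SPARQL endpoint",
               parent_id="dataset-cxe",
               media_type="application/sparql-results+json",
               access_url="http://localhost:3030/pheno/sparql")
tree = build_fdp(root, catalogs, [dataset], [dist])
embed_investigation(dataset, fx.investigation, policy)

with tempfile.TemporaryDirectory() as tmp:
    paths = emit_tree(tree, tmp, policy)
    result = crawl_fdp(policy.mint("fdp", "fdp-root"), file_fetcher(paths))

print(f"crawled {sum(1 for _ in result.root.walk())} nodes, "
      f"{len(result.root.children)} catalogs")
summary = result.summaries["dataset-cxe"]
print("dataset found from embedded metadata alone:")
print("  investigation:", summary.investigation_title)
print("  studies:", ", ".join(summary.study_ids))
print("  observed variables:", ", ".join(summary.variable_ids))
print(f"  {summary.material_count} biological materials from "
      f"{', '.join(summary.material_sources)}")
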