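"""Reproduce the published pathway overrepresentation arithmetic.

The packaged fixtures carry the printed inputs of the pathway analyses
(reference size N = 20972; list sizes n = 385 and 158; per-category
reference counts K and observed hits k).  The binomial test recomputes
every expected count, fold enrichment and Bonferroni-corrected p-value.
"""

from importlib import resources

from immunosig import score_pathway_table
from immunosig.enrichment import rows_to_frame

for tag, fname in (("377-gene list", "panther_pathways_377.tsv"),
                   ("157-gene list", "panther_pathways_157.tsv")):
    path = str(resources.files("immunosig.data") / fname)
    rows = score_pathway_table(path, bonferroni_count=158)
    frame = rows_to_frame(rows)
    print(f"\n=== {tag} ===")
    print(frame[["category", "observed", "expected", "direction",
                 "fold_enrichment", "p_corrected"]].head(6).to_string(index=False))
# JAK/STAT: 6 observed vs 0.31 expected -> 19.23-fold enriched, p = 1.50E-04
# after Bonferroni correction over the 158 categories tested.
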