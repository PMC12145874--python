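"""phresp: growth and transcriptomic response of strains across pH conditions.

Estimates per-period exponential growth rates from fluorescence series,
contrasts them nonparametrically across pH conditions, scores genes by signed
ln(FDR), runs three complementary gene-set enrichment analyses (functional
class scoring, over-representation, and the unidirectional gene-set
criterion), combines them into composite affected-set calls, and clusters
strain-pH enrichment groups by square-root-transformed Jaccard distance.
A seeded synthetic-data generator emulates every input contract so the whole
pipeline is testable without sequencing data.
"""

__version__ = "0.1.0"

from .growth import (  # noqa: F401
    GrowthSeries,
    GrowthRateRecord,
    GrowthTestResult,
    growth_rate,
    period_rates,
    test_ph_effect,
    classify_growth_pattern,
)
from .genesets import (  # noqa: F401
    GeneSetCollection,
    OntologyDAG,
    propagate_ancestors,
    restrict_to_universe,
    read_gmt,
    write_gmt,
)
from .scoring import DETable, cpm_filter, slfdr, call_degs, sample_distances  # noqa: F401
from .enrichment import (  # noqa: F401
    EnrichmentCall,
    CompositeCall,
    fcs,
    ora,
    ugs,
    adjust_and_combine,
    run_enrichment,
)
from .clustering import (  # noqa: F401
    EnrichmentGroup,
    build_groups,
    group_label,
    jaccard_sqrt_distance,
    order_groups,
    export_heatmap,
)
from .pipeline import RunConfig, run_pipeline  # noqa: F401
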