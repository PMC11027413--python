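"""Exceptions and reason codes shared across the pipeline stages."""


class PolkinError(Exception):
    """Base class for pipeline errors."""


class SkippedGene(PolkinError):
    """A gene was excluded from an analysis; carries a machine-readable reason.

    Reason codes in use:

    - ``length<=2kb``        gene too short for the pause-release filters
    - ``neighbor<=1kb``      nearest gene closer than 1 kb
    - ``promoter_unoccupied`` no polymerase signal called at the promoter
    - ``zero_promoter``      promoter window density is zero
    - ``zero_reference``     RI reference region density is zero
    - ``neighbor_too_close`` truncated downstream window shorter than 200 bp
    - ``missing>60%``        more than 60% of 50-bp bins have no signal
    - ``non-monotone``       wave fronts not strictly increasing in time
    - ``uncalled``           wave front could not be called at a timepoint
    """

    def __init__(self, gene_id: str, reason: str):
        self.gene_id = gene_id
        self.reason = reason
        super().__init__(f"{gene_id}: {reason}")


# canonical reason-code constants
LENGTH_FILTER = "length<=2kb"
NEIGHBOR_FILTER = "neighbor<=1kb"
UNOCCUPIED = "promoter_unoccupied"
ZERO_PROMOTER = "zero_promoter"
ZERO_REFERENCE = "zero_reference"
NEIGHBOR_TOO_CLOSE = "neighbor_too_close"
MISSING_BINS = "missing>60%"
NON_MONOTONE = "non-monotone"
UNCALLED = "uncalled"
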