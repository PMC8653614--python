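"""Discovery and evaluation of clinical subtypes of Alzheimer's disease
from categorical EHR feature tables.

Pipeline: synthetic or user-supplied event tables -> cohort selection and
one-hot feature construction -> multiple correspondence analysis -> four
clustering methods (k-means, kernel k-means, affinity propagation, latent
class analysis) -> evaluation by cluster structure, stability, replicability
and clinical utility -> cluster characterisation and cross-method comparison.
"""

from . import (  # noqa: F401
    clustering,
    comparison,
    evaluation,
    features,
    mca,
    outcomes,
    pipeline,
    synthetic,
)

__version__ = "0.1.0"

__all__ = [
    "clustering",
    "comparison",
    "evaluation",
    "features",
    "mca",
    "outcomes",
    "pipeline",
    "synthetic",
]
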