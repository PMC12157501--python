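"""srnaclass: discovery and classification of noncanonical small-RNA loci.

Integrates depletion-response differential abundance (Microprocessor,
Dicer, Pol III), hairpin stem-length classification, Pol III type-II
promoter architecture scanning, untemplated 3' tailing/isoform analysis,
and Microprocessor cleavage-efficiency scoring into per-locus biogenesis
class labels, with a synthetic-data generator for fully ground-truthed
benchmarking.
"""

__version__ = "0.1.0"

from .classify import (  # noqa: F401
    ClassLabel,
    EvidenceVector,
    Thresholds,
    chip_overlap,
    classify_locus,
    cleavage_score,
)
from .diffabund import bh_adjust, diff_table, log2_fold_change, nb_test, spike_size_factors  # noqa: F401
from .hairpin import fold_maxpair, hairpin_report, parse_dotbracket  # noqa: F401
from .io_formats import CountMatrix, GenomeSeq, Interval, Locus  # noqa: F401
from .pipeline import RunConfig, demo_config, make_demo, run_all  # noqa: F401
from .pol3 import MotifDef, ScanConfig, find_t_runs, pol3_report, scan_iupac  # noqa: F401
from .synthetic_data import (  # noqa: F401
    SimConfig,
    build_genome_and_loci,
    simulate_counts,
    simulate_reads,
)
from .tailing import ArmIndex, asymmetry_test, call_tail, call_tails, tailing_profile  # noqa: F401
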