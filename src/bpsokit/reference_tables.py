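"""Built-in clinical example tables.

Printed summary tables from a two-arm adrenal-tumor MRI study: a control arm
read with conventional MRI and an observation arm read with swarm-optimized
MRI, each scored against surgical pathology in 60 patients.  The raw images
were never deposited; these count tables are the only reproducible record,
and the reproduction report recomputes every derivable statistic from them.

``PUBLISHED`` holds the values as printed (percentages on the 0-100 scale).
Note the printed kappas are not recoverable from the printed 2x2 tables by
the standard Cohen formula; see :func:`bpsokit.report.reproduce_reference_tables`.
"""

from .diagnostics import ConfusionTable, LocationCounts

#: control arm, tumor nature (malignant vs benign) against pathology
CONTROL_CONFUSION = ConfusionTable(tp=20, fp=5, fn=20, tn=15)

#: observation arm, tumor nature against pathology
OBSERVATION_CONFUSION = ConfusionTable(tp=30, fp=5, fn=6, tn=19)

#: control arm, tumor-location counts (imaging, pathology) per type
CONTROL_LOCATION = LocationCounts(
    [
        ("metastatic", 14, 19),
        ("stromal", 17, 23),
        ("medullary", 21, 11),
        ("cortical", 11, 7),
    ]
)

#: observation arm, tumor-location counts per type
OBSERVATION_LOCATION = LocationCounts(
    [
        ("metastatic", 17, 18),
        ("stromal", 20, 20),
        ("medullary", 14, 16),
        ("cortical", 8, 6),
    ]
)

#: statistics as printed in the study (percent scale; kappa unitless)
PUBLISHED = {
    "control": {
        "sensitivity": 50.0,
        "specificity": 75.0,
        "accuracy": 58.33,
        "kappa": 0.45,
        "location_similarity": 65.9,
    },
    "observation": {
        "sensitivity": 83.33,
        "specificity": 79.17,
        "accuracy": 81.67,
        "kappa": 0.69,
        "location_similarity": 89.24,
    },
}
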