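"""Sample naming for the tumor/xenograft series.

The series is ordered by acquisition time: patient blood (germline control),
primary tumor, recurrent tumor, first- and second-generation xenograft.  The
blood sample is a control only -- it never enters timeline ordering.
"""

BLOOD = "blood"
PRIMARY = "primary"
RECURRENT = "recurrent"
XENO1 = "xeno1"
XENO2 = "xeno2"

#: Full series order, blood first.
SAMPLES: tuple[str, ...] = (BLOOD, PRIMARY, RECURRENT, XENO1, XENO2)

#: Tumor samples in temporal order (timeline ordering operates on these).
TUMOR_SAMPLES: tuple[str, ...] = (PRIMARY, RECURRENT, XENO1, XENO2)
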