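# External reference inputs (not redistributed)

The reference-reproduction test in `tests/test_acceptance.py`
(`TestReferenceMotifSplit`) needs files that must be downloaded separately
and placed in this directory:

| file | source |
| --- | --- |
| `mm10.fa` (+ `.fai` index) | UCSC / Ensembl mouse genome assembly mm10 |
| `ENCFF929RJU.bed` | ENCODE portal — CTCF optimal IDR peaks, G1E-ER4+E2 |
| `ENCFF972VNL.bed` | ENCODE portal — TAL1 optimal IDR peaks, G1E-ER4+E2 |
| `CTCF_MOUSE.H11MO.0.A.pcm` | HOCOMOCO v11 mouse count matrix |
| `TAL1_MOUSE.H11MO.0.A.pcm` | HOCOMOCO v11 mouse count matrix |

Without them the reproduction test fails with a message pointing here; all
other tests are self-contained.
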