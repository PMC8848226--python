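"""Scoring the study instruments: SEQ, NDI, MMSE and VAS."""

from cervigame import (MmseRecord, NdiResponse, SeqResponse, mmse_classify,
                       score_ndi, score_seq, validate_vas)

# A satisfied participant: high agreement on the positive items, low raw
# values on the reverse-keyed difficulty/discomfort block (Q7-Q10, Q12, Q13)
seq = SeqResponse([5, 4, 4, 5, 4, 3, 2, 1, 1, 2, 4, 1, 2])
print(f"SEQ total          : {score_seq(seq)} / 65 (13 = worst, 65 = best)")

ndi = NdiResponse([2, 1, 2, 3, 1, 2, 2, 1, 2, 1])
res = score_ndi(ndi)
print(f"NDI                : {res['raw']}/50 raw = {res['percent']:.0f}% disability")

mmse = mmse_classify(MmseRecord(score=28, age=79))
print(f"MMSE               : bracket={mmse['bracket']}, cutoff={mmse['cutoff']}, "
      f"below={mmse['below_cutoff']}")

vas = validate_vas(4.5)
print(f"VAS                : {vas.value} (poor pain control: {vas.poor_control})")
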