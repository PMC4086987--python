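# Canonical inter-patient division of the MIT-BIH Arrhythmia Database
# (de Chazal, O'Dwyer & Reilly 2004): 22 training records (DS1), 22 test
# records (DS2), 4 paced records excluded per the AAMI recommendation.
# Editable data, not code: a different corpus can ship its own copy.
ds1:
  ["101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
   "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
   "223", "230"]
ds2:
  ["100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
   "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
   "233", "234"]
excluded:
  ["102", "104", "107", "217"]
# Annotation symbol -> studied class; every other symbol maps to OTHER.
symbol_map:
  "N": NORM
  "L": LBBB
  "R": RBBB
# Channel order of the study data: lead A is channel 0, lead B channel 1.
sampling_rate_hz: 360
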