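code,label,description
2,cannot_determine,Series could not be curve-fit (e.g. fewer than 4 distinct concentrations)
13,inactive_clear,Inactive with modeled |top| < 0.8 times the cutoff
15,inactive_borderline,Inactive but modeled |top| >= 0.8 times the cutoff (borderline inactivity)
36,active_borderline_ac50_below,Active with |top| <= 1.2*cutoff and AC50 at or below the lowest tested concentration
37,active_borderline_informative,Active with |top| <= 1.2*cutoff and AC50 and AC95 inside the tested range
38,active_borderline_ac95_above,Active with |top| <= 1.2*cutoff and AC95 at or beyond the highest tested concentration
40,active_moderate_ac50_below,Active with |top| > 1.2*cutoff and AC50 at or below the lowest tested concentration
41,active_moderate_informative,Active with |top| > 1.2*cutoff and AC50 and AC95 inside the tested range
42,active_moderate_ac95_above,Active with |top| > 1.2*cutoff and AC95 at or beyond the highest tested concentration
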