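>tetramer_domain_synthetic | SYNTHETIC 68-mer stand-in for the NHR2-like construct; 3 Trp, 2 Tyr, 0 Cys; average MW 8547 Da; eps280 19480 /M/cm
DAHFEHPSWIQMFNFMVSHFEFWFREPEFNFMDNTPPNKRYDEKSNHWMPNKEFRYFEEDKPSSAPQI
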