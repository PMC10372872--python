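>MT3_HUMAN P25713 Metallothionein-3 (growth-inhibitory factor), canonical sequence
MDPETCPCPSGGSCTCADSCKCEGCKCTSCKKSCCSCCPAECEKCAKDCVCKGGEAAEAE
AEKCSCCQ
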