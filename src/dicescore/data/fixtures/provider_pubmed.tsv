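# synthetic offline provider table: raw_query <TAB> comma-separated record ids
tyrosine aminotransferase and malaria	rec-tat-malaria-1
hemoglobin S and malaria	rec-hbs-malaria-1,rec-hbs-malaria-2
ATP2B4 and malaria	rec-atp2b4-malaria-1
MARVELD3 and malaria
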