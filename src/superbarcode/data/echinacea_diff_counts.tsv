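# Published pairwise base-difference counts among the nine Echinacea
# chloroplast genomes (lower triangle of the printed table; symmetric).
taxon	paradoxa	atrorubens	sanguinea	pallida	angustifolia	tennesseensis	laevigata	speciosa	purpurea
paradoxa	0	181	345	273	672	787	772	768	849
atrorubens	181	0	308	276	727	837	835	830	910
sanguinea	345	308	0	247	685	827	813	827	908
pallida	273	276	247	0	629	765	764	767	842
angustifolia	672	727	685	629	0	711	677	689	811
tennesseensis	787	837	827	765	711	0	445	309	469
laevigata	772	835	813	764	677	445	0	365	478
speciosa	768	830	827	767	689	309	365	0	350
purpurea	849	910	908	842	811	469	478	350	0
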