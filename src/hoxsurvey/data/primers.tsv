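# Degenerate primer table for the Hox homeobox/exon1 PCR survey.
# direction: forward|reverse (reverse primers are written 5'->3' and bind the sense strand's complement)
# targets: comma-separated tokens; PGn or PGa-PGb denote whole paralogue groups, letterdigit tokens (A5) denote single genes
# aa_motif: sense-strand amino-acid motif encoded at the binding site; 5UTR marks untranslated-region primers (no motif)
# product_len: nominal product size in bp when paired as in the survey ("" where defined only by pairing); ranges for exon1 products
# tier: general (first-round PG-set primers), pg_specific, member_specific
# pairs_with: explicit pairing override (| separated); empty = pair by shared targets
name	sequence	direction	targets	aa_motif	product_len	tier	region	pairs_with	note
HoxF1	TNGARYTNGARAARGARTTYCA	forward	PG1-PG7	LELEKEFH	125	general	homeobox		universal for PG1-PG7
HoxF1N1	CARACNYTNGARYTNGARAARGARTT	forward	PG1-PG10	QTLELEKEF	128	general	homeobox		universal for PG1-PG10
HoxF1N2	CARGTNACNGARYTNGARAARGARTT	forward	PG1-PG10	QVTELEKEF	128	general	homeobox		universal for PG1-PG10; motif printed as QLTELEKEF but the oligo encodes V at the second position
HoxF7S	CARACNTAYACNMGNTAYCARAC	forward	PG5-PG7	QTYTRYQT	149	general	homeobox		universal for PG5-PG7
HoxF8	TNGARAARGARTTYYTNTTYAA	forward	PG8-PG10	LEKEFLFN	120	general	homeobox		universal for PG8-PG10
HoxF8N	TNGARYTNGARAARGARTTYYT	forward	PG8-PG10	LELEKEFL	125	general	homeobox		universal for PG8-PG10
HoxF9	DSNMGNAARAARVGNTGYCCNTA	forward	PG9-PG11	TRKKRCPY	164	general	homeobox		universal for PG9-PG11
HoxF1S	AAYTTYACNACNAARCARYTNAC	forward	PG1	NFTTKQLT	149	pg_specific	homeobox		universal for PG1
HoxF2S	MGGACNGCNTAYACNAAYACNCA	forward	PG2	RTAYTNTQ	152	pg_specific	homeobox		specific for PG2
HoxF3S	GCNTAYACNAGYGCNCARYTNGT	forward	PG3	AYTSAQLV	149	pg_specific	homeobox		specific for PG3
HoxF3S1	MGVCCNMGVMGVBTNGARATGGC	forward	PG3	RPRRVEMA	80	pg_specific	homeobox		specific for PG3
HoxF4S	ACNGCNTAYACNMGNCARCARGT	forward	PG4	TAYTRQQV	152	pg_specific	homeobox		specific for PG4
HoxF5S	GGNAARMGSGCNMGSACNGC	forward	A5,B5	GKRARTA	165	pg_specific	homeobox		specific for A5, B5
HoxFC5	AARCGNTCYMGAACNAGYTAYAC	forward	C5	KRSRTSYT	160	member_specific	homeobox		specific for C5
HoxF8S	GARAARGARTTYYTNTTYAAYCC	forward	PG8	EKEFLFNP	116	pg_specific	homeobox		specific for PG8
HoxF9S	GARAARGARTTYYTNTTYAAYATG	forward	PG9	EKEFLFNM	116	pg_specific	homeobox		specific for PG9
HoxF10S	AARMGNTGYCCNTAYACNAARCA	forward	PG10	KRCPYTKH	152	pg_specific	homeobox		specific for PG10
HoxF11	GARYTNGARMGNGARTTYTTYTT	forward	PG11	ELEREFFF	122	general	homeobox		specific for PG11 (first-round PG11 set)
HoxF12	DSNMGNAARAARVGNAARCCNTA	forward	PG12	SRKKRKPY	164	general	homeobox		specific for PG12 (first-round PG12 set)
HoxF12C	AARCCNTAYTCNAARYTNCARAT	forward	C12	KPYSKLQL	149	member_specific	homeobox		specific for C12
HoxF12D	AARCCNTAYACNAARCARCARAT	forward	D12	KPYTKQQI	149	member_specific	homeobox		specific for D12
HoxF12N1	KCNMGVAARAARMGVAARCCSTA	forward	PG12	SRKKRKPY	164	general	homeobox		specific for PG12 (first-round PG12 set)
HoxF12N2	KCNMGVAARAARMGVAARCCWTA	forward	PG12	SRKKRKPY	164	general	homeobox		specific for PG12 (first-round PG12 set)
HoxF12N3	KCNMGVAARAARMGVAARACNTA	forward	PG12	SRKKRKTY	164	general	homeobox		specific for PG12 (first-round PG12 set)
HoxF13A	GGNMGNAARAARMGNGTNCCNTA	forward	A13,C13,D13,PG14	GRKKRVPY	164	general	homeobox		specific for PG13(A,C,D) (first-round PG13 set); also paired with HoxR14
HoxF13B	GGNMGNAARAARMGNATHCCNTA	forward	B13,PG14	GRKKRIPY	164	general	homeobox		specific for PG13(B) (first-round PG13 set); also paired with HoxR14
HoxF13A1	CARYTRAARGARCTNGARMGNGARTA	forward	A13	QLKELEREY	128	member_specific	homeobox		specific for PG13(A)
HoxF13B1	CARYTRAARGARCTNGARAANGARTA	forward	B13,C13,D13	QLKELENEY	128	pg_specific	homeobox		specific for PG13(B,C,D)
HoxR1	TTCATNCKNCKRTTYTGRAACCA	reverse	PG1-PG12	WFQNRRMK		general	homeobox		universal for PG1-PG12
HoxR13	TTNACNCKNCKRTTYTGRAACCA	reverse	PG13	WFQNRRVK		general	homeobox		specific for PG13
HoxR14	TCNGGNGTNAGRAANCGRTTYTC	reverse	PG14	ENRFLTPE	89	general	homeobox	HoxF13A|HoxF13B	specific for PG14, used with HoxF13A/HoxF13B
HoxB1(5'E1)F	GACATASTRYCNAAAGGTTGTAG	forward	B1	5UTR	590-630	member_specific	exon1		forward primer for HoxB1
HoxB1(E1)R	TTAACYTTCATCCANTCRAANGT	reverse	B1	TFDWMKVK		member_specific	exon1		reverse primer for HoxB1
Hox2S(E1)F	GAATTYGAGMGRGARATHGGNTT	forward	PG2	EFEREIGF	270-300	pg_specific	exon1		forward primer for PG2
Hox2S(E1)R	YTTYTTCTCYTTCATCCANGG	reverse	PG2	PWMKEKK		pg_specific	exon1		reverse primer for PG2
Hox3S(E1)F	ATGCARAAARCRRCNTAYTAYGA	forward	PG3	MQKATYYD	400-480	pg_specific	exon1		forward primer for PG3
HoxC3(E1)F	ATGCAAAARGSTCYYTAYTAYGA	forward	C3	MQKGPYYE	400-480	member_specific	exon1		forward primer for HoxC3
HoxA3(E1)F	GCGACCTACTAYGAYAGYTCNGC	forward	A3	ATYYDSSA	390-470	member_specific	exon1		forward primer for HoxA3
HoxD3(E1)F	ATGCAGAAARCNGCYTAYTAYGA	forward	D3	MQKTAYYD	400-480	member_specific	exon1		forward primer for HoxD3
Hox3S(E1)R	TCYTTCATCCANGGRAADATNTG	reverse	PG3	QIFPWMKE		pg_specific	exon1		reverse primer for PG3
HoxB6(5'E1)F	AWACTRCTAATAGCTAAASCRCT	forward	B6	5UTR	480-510	member_specific	exon1		listed as reverse primer for HoxB6 in the source table
Hox6S(E1)R	GARTTCATCCKYTGCATCCANGG	reverse	PG6	PWMQRMNS		pg_specific	exon1		reverse primer for PG6
HoxB7(5'E1)F	CTCGTAAAACCGACACTAAAACG	forward	B7	5UTR	440-460	member_specific	exon1		forward primer for HoxB7
Hox7S(E1)R	CATCCARGGGTADATNCGRAA	reverse	PG7	FRIYPWM		pg_specific	exon1		reverse primer for PG7
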