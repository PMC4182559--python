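protein	condition	line	grade
pSTAT3	GF	BTIC-1	+
pSTAT3	GF	BTIC-2	+
pSTAT3	GF	BTIC-3	++
pSTAT3	GF	BTIC-4	+
pSTAT3	GF	BTIC-5	0
pSTAT3	GF	BTIC-6	0
pSTAT3	GF	BTIC-7	++
pSTAT3	GF	BTIC-8	0
pSTAT3	GF	BTIC-9	++
pSTAT3	GF	BTIC-10	0
pSTAT3	GF	BTIC-11	0
pSTAT3	GF	BTIC-12	+
pSTAT3	GF	BTIC-13	+
pSTAT3	GF	BTIC-14	+
pSTAT3	GF	BTIC-15	n.S.
pSTAT3	GF	BTIC-16	0
pSTAT3	GF	BTIC-17	++
pSTAT3	GF	BTIC-18	+
pAKT	GF	BTIC-1	+
pAKT	GF	BTIC-2	0
pAKT	GF	BTIC-3	++
pAKT	GF	BTIC-4	+
pAKT	GF	BTIC-5	0
pAKT	GF	BTIC-6	+
pAKT	GF	BTIC-7	+
pAKT	GF	BTIC-8	0
pAKT	GF	BTIC-9	+
pAKT	GF	BTIC-10	++
pAKT	GF	BTIC-11	+
pAKT	GF	BTIC-12	+
pAKT	GF	BTIC-13	++
pAKT	GF	BTIC-14	+
pAKT	GF	BTIC-15	++
pAKT	GF	BTIC-16	++
pAKT	GF	BTIC-17	++
pAKT	GF	BTIC-18	++
pERK1/2	GF	BTIC-1	+
pERK1/2	GF	BTIC-2	0
pERK1/2	GF	BTIC-3	0
pERK1/2	GF	BTIC-4	0
pERK1/2	GF	BTIC-5	0
pERK1/2	GF	BTIC-6	+
pERK1/2	GF	BTIC-7	0
pERK1/2	GF	BTIC-8	+
pERK1/2	GF	BTIC-9	+
pERK1/2	GF	BTIC-10	+
pERK1/2	GF	BTIC-11	0
pERK1/2	GF	BTIC-12	0
pERK1/2	GF	BTIC-13	+
pERK1/2	GF	BTIC-14	0
pERK1/2	GF	BTIC-15	++
pERK1/2	GF	BTIC-16	0
pERK1/2	GF	BTIC-17	0
pERK1/2	GF	BTIC-18	+
pSTAT3	Sunitinib	BTIC-1	--
pSTAT3	Sunitinib	BTIC-2	--
pSTAT3	Sunitinib	BTIC-3	--
pSTAT3	Sunitinib	BTIC-4	--
pSTAT3	Sunitinib	BTIC-5	u.e.
pSTAT3	Sunitinib	BTIC-6	-
pSTAT3	Sunitinib	BTIC-7	-
pSTAT3	Sunitinib	BTIC-8	-
pSTAT3	Sunitinib	BTIC-9	0
pSTAT3	Sunitinib	BTIC-10	n.S.
pSTAT3	Sunitinib	BTIC-11	-
pSTAT3	Sunitinib	BTIC-12	-
pSTAT3	Sunitinib	BTIC-13	0
pSTAT3	Sunitinib	BTIC-14	0
pSTAT3	Sunitinib	BTIC-15	n.S.
pSTAT3	Sunitinib	BTIC-16	u.e.
pSTAT3	Sunitinib	BTIC-17	0
pSTAT3	Sunitinib	BTIC-18	0
pAKT	Sunitinib	BTIC-1	0
pAKT	Sunitinib	BTIC-2	-
pAKT	Sunitinib	BTIC-3	-
pAKT	Sunitinib	BTIC-4	-
pAKT	Sunitinib	BTIC-5	-
pAKT	Sunitinib	BTIC-6	0
pAKT	Sunitinib	BTIC-7	-
pAKT	Sunitinib	BTIC-8	-
pAKT	Sunitinib	BTIC-9	0
pAKT	Sunitinib	BTIC-10	-
pAKT	Sunitinib	BTIC-11	-
pAKT	Sunitinib	BTIC-12	0
pAKT	Sunitinib	BTIC-13	-
pAKT	Sunitinib	BTIC-14	-
pAKT	Sunitinib	BTIC-15	-
pAKT	Sunitinib	BTIC-16	u.e.
pAKT	Sunitinib	BTIC-17	0
pAKT	Sunitinib	BTIC-18	-
pERK1/2	Sunitinib	BTIC-1	0
pERK1/2	Sunitinib	BTIC-2	--
pERK1/2	Sunitinib	BTIC-3	0
pERK1/2	Sunitinib	BTIC-4	0
pERK1/2	Sunitinib	BTIC-5	0
pERK1/2	Sunitinib	BTIC-6	-
pERK1/2	Sunitinib	BTIC-7	-
pERK1/2	Sunitinib	BTIC-8	0
pERK1/2	Sunitinib	BTIC-9	0
pERK1/2	Sunitinib	BTIC-10	0
pERK1/2	Sunitinib	BTIC-11	-
pERK1/2	Sunitinib	BTIC-12	-
pERK1/2	Sunitinib	BTIC-13	0
pERK1/2	Sunitinib	BTIC-14	0
pERK1/2	Sunitinib	BTIC-15	-
pERK1/2	Sunitinib	BTIC-16	u.e.
pERK1/2	Sunitinib	BTIC-17	0
pERK1/2	Sunitinib	BTIC-18	0
pSTAT3	Sunitinib+GF	BTIC-1	--
pSTAT3	Sunitinib+GF	BTIC-2	--
pSTAT3	Sunitinib+GF	BTIC-3	--
pSTAT3	Sunitinib+GF	BTIC-4	--
pSTAT3	Sunitinib+GF	BTIC-5	u.e.
pSTAT3	Sunitinib+GF	BTIC-6	--
pSTAT3	Sunitinib+GF	BTIC-7	--
pSTAT3	Sunitinib+GF	BTIC-8	-
pSTAT3	Sunitinib+GF	BTIC-9	--
pSTAT3	Sunitinib+GF	BTIC-10	n.S.
pSTAT3	Sunitinib+GF	BTIC-11	-
pSTAT3	Sunitinib+GF	BTIC-12	0
pSTAT3	Sunitinib+GF	BTIC-13	--
pSTAT3	Sunitinib+GF	BTIC-14	-
pSTAT3	Sunitinib+GF	BTIC-15	n.S.
pSTAT3	Sunitinib+GF	BTIC-16	u.e.
pSTAT3	Sunitinib+GF	BTIC-17	--
pSTAT3	Sunitinib+GF	BTIC-18	0
pAKT	Sunitinib+GF	BTIC-1	--
pAKT	Sunitinib+GF	BTIC-2	-
pAKT	Sunitinib+GF	BTIC-3	--
pAKT	Sunitinib+GF	BTIC-4	-
pAKT	Sunitinib+GF	BTIC-5	--
pAKT	Sunitinib+GF	BTIC-6	-
pAKT	Sunitinib+GF	BTIC-7	--
pAKT	Sunitinib+GF	BTIC-8	-
pAKT	Sunitinib+GF	BTIC-9	-
pAKT	Sunitinib+GF	BTIC-10	--
pAKT	Sunitinib+GF	BTIC-11	-
pAKT	Sunitinib+GF	BTIC-12	-
pAKT	Sunitinib+GF	BTIC-13	--
pAKT	Sunitinib+GF	BTIC-14	--
pAKT	Sunitinib+GF	BTIC-15	--
pAKT	Sunitinib+GF	BTIC-16	0
pAKT	Sunitinib+GF	BTIC-17	--
pAKT	Sunitinib+GF	BTIC-18	-
pERK1/2	Sunitinib+GF	BTIC-1	-
pERK1/2	Sunitinib+GF	BTIC-2	--
pERK1/2	Sunitinib+GF	BTIC-3	0
pERK1/2	Sunitinib+GF	BTIC-4	-
pERK1/2	Sunitinib+GF	BTIC-5	0
pERK1/2	Sunitinib+GF	BTIC-6	-
pERK1/2	Sunitinib+GF	BTIC-7	-
pERK1/2	Sunitinib+GF	BTIC-8	-
pERK1/2	Sunitinib+GF	BTIC-9	-
pERK1/2	Sunitinib+GF	BTIC-10	--
pERK1/2	Sunitinib+GF	BTIC-11	-
pERK1/2	Sunitinib+GF	BTIC-12	+
pERK1/2	Sunitinib+GF	BTIC-13	-
pERK1/2	Sunitinib+GF	BTIC-14	0
pERK1/2	Sunitinib+GF	BTIC-15	--
pERK1/2	Sunitinib+GF	BTIC-16	+
pERK1/2	Sunitinib+GF	BTIC-17	0
pERK1/2	Sunitinib+GF	BTIC-18	0
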