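>DFR_synthetic_1
CKMCVAGCVDCNSLLGWACRQWTFWVECFQCMLIRRLITGTQHSIAFHEPVTCKRWFPMVKYFAPEGANHTNFVYEHREA
TGVEEMTQSPFPQVWTFSNNTFSCKCMSYSTVLRCMMGQKYSPQSNSDWSNQNVTRGTYKNSQADNALDNRCTAGSWMAA
EPDKNEHDNDTDHLMNGPQYTPAKTLSCWHMGKFANWPGAYWLLCICSFVTMVYPQTSIGCLYFIMMMHQAWVENWWMRF
RKVRKPQEWPSCPHACCWDFVERDTDYRKTERARMIVCGIGDRMMYHDFQSNLKNWYLFMFHAQWRWFNESIAPFKNHAR
DSGVDQIFKFVIHIVRSSVT
>DFR_synthetic_2
CVMCNWGCVDCNSLVGWACKSWHFWVECMQCMLIRRLITATNHSIAFHEPVECERWCPNVKYGAPEGANHTNFPYWYRVA
YGVEEMRYMPFGQVWTFSNNTFSVGCMSYSTVLFCMMGQKYSPQSNVDFSNGNVTPLTTINSTADNALDNRCTAGSWMVA
EDDKNECDNDTDHEMNGPWYTPAKLPSCAHMGKFANSPAPYWLLCICSFWTMVCPQFKIGCGYFIMMMHQPWVEMWWTIF
RKVRKPQEWPSCPKRCCWDTVEGDTDTEKAERARMIACGCGDHMMYHIFQDNLTNWYNFMFHAMWRWFNESHWNFLNHAR
FSGVDYIFKMVIHRVRSSVT
>DFR_synthetic_3
CKVCNAPVVKCNSLVGWACRYWHFWVCCFQCMLIRMLITATFHSIAAHEPVECKRWFPMVKYGAPEGATHFNFVYWHTVA
YGVGEMTYKPFGQVWTFKNNTFSCTPMSYSTVLRCMMGQKYSPQSNVDFSNQNVTRGTTTNSEADNALDNWCTAGSWMVA
EDDKNEHDNDDDHEMNGPQYFPAKLLSYWHKGKFANSTAAYWLLCICSFWTIVYPQFKIGCGYGIMMMHQPKEEDWWMRF
RKVGKPQEWPSCPKRCREDPVERDTSTEKVERARMIVCGIGFRMMYHDPQDNLTNWYGFMFHADMRWFEESIAPFLNHAR
DSGVDQIFKMVIHKVRSSVT
>DFR_synthetic_4
CKMCNAGCVDCNSLVGWACRQWHLWVECFQMKLIRRMDTATNHSIAFHEPVECKMWFPMVKYGAPEGANHSNFVYWDHVA
IGLEEMRYMPFGEEWHFCNGTFSCTCMSYFTVLRCMMGQKPSPQSPVDFSNQNVTRGTTINSEADNALDNRCTAGSLMVA
EDDKCEHDNDTDHEMNGPQYTPAKTLSCFDMGKFANSPAAYWLLCICSFWTMVTRQFKIGMGYFIMMMHQPWVENWWMRF
RKVRKPQEPPSCPKRCCWDPVERDTTTEKAERARMIVCGIGDRMMPHDFQANLTNWYGFMHHAQWRWFNESIAPFNNHAI
DSGVDQKFKMEFHSVRSSLT
>DFR_synthetic_5
CKMCNAACVDCNSPVGWQCGQWHFWVECWQCMLIRRLITATNHSIAFHEPVECKRWFLMVKYGAPEGANHGNFVYWHMVA
YGVEECGYMPFGQVWTFSNNGFSCMCESYNTVLRCMMGQKYSPQSNCDFSNQNVTRGTTINSEADNALDNRCTAGSWMVA
EKDKNEHDNLTDHEMNGPQYTPAKTLSCWHMGKFANPPAAYWLLCICSFATMVYPWFKIGCGYFIPMMHQPWVTNWWMRF
RCVRKPIRWLSCPKRCCWDPSERQTDTEPVERARMIVCGIGDRMMYSDFQDNLTNWYGFMFHAQWRWFNESIAIFLNHAR
DSMTDQMFKMVIHGVRSNVT
>DFR_synthetic_6
CKMCNGGCVDCNSLVGWACRQWCFWVGEFQCMLIHRRITATNESIAWHEPVECKRWFSMVKYGAPEGANHTNFVLFHEVA
YGVEEMTYMPFGQVWTFHTNTFSCTCSSYSTVLRYHMAGKYSPQSNVDFSNQNFTRGMTINHEADNCLDNRCTAGSWCVA
EDDKNEHDNDTDMEMNGPQYTPAKTLSCWHMGKFANSPAAYWLVCICSFNTMVYPQTWIGCGYFIMMMHQPWVENWWMSS
RKVRKPQMWPICPKRCCWDPVERDCDTEKVERARMTVCGIGDRMMSHDFQANLYNWEGFMFHAQWRWFINSIAPFGNHAR
DSGVDQIVKEVIEKNHSSVT
>DFR_synthetic_7
CKMCNWGCVDCNSNVRWACRQWHFWVECFQCMLIRRLITATNHSIAMHEPVECKRWFPMVKYGAPEGAWHTAFVYWHRVL
YGVEEMTYMPFGQVSMFSNNTWDCGCMSYSTVLRCWMGQKYSPQSNVDFSFQNVTRGTTINSEADNALDNRWTAGSFMVA
GDDKNEVINVTDHEMNGHQYTPAKTYSCWHMGKFANSPQAIWLLCISSYWTMCYPQFKIRCGYFHMMMHQPWVENWWMRF
RKVRKPQEWPSSPKRLCWDVVERRTDHEKVERARMIVCGIGDRMMYHDFQDNLTNWAGFMFHAQWRWDSESIAPMGNHAR
DSGVDQIFHMVIHKVASPPK
>DFR_synthetic_8
GKMCNAGCVDCNSLVGWACRQWHFWVECFQCMLIRVLITATNSSIAFHEPVEYKRWFPMVKYGAPEGAEHTNFVYTHRVA
YGVEEMTYMPFGPVWTFPANTFSCACMSYATVLRCMMGQKYSPQSNVDFSNQNVTHGTTINSDADNALDNRCTAGSWMVA
MDDVNEHDYHTRHEMNTPDYTPAKTLSCWHMGKNANSPWAYWYLCICSFWTMVYPQFKILCGYFIMMMHQPWVILWWMRF
RKVRDPTEWASHPKRCCWDPVERDTDTEKVERATMIVCGICDRCMYHDDQDHLTNIYGFMFHACWRWFNESIKPGLNHAR
DSGVRQIGKMVDHKVRSSVT
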