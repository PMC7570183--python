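>STS_synthetic_1
CWKIDNNHCYHFIPYCPNVCYLDITWTMCGWMTLNKKQCHLLTWATALWVENNVQWLSFKHTIWISSLLHRSYNPLHMLG
RFSVEHMSWCYSTQKRMIINPNMANENLSRSIFKELHLQCSAICYGLAPKSDKKPSPMEFFVDPTDGYKRADNDINNFNS
QCSIAQHVGWLHSTQYPQQCEYKSNFLKLYWEVGWQLCRWLYAQPEMYKYIWHVNGPCVWKTFNCMCIMTFCTVMVNNWY
DMSEYSSRYHGWSNGRLLKVWVKAHGKLFRYFLIKFVHDWGGISTITVATKNSTDLDYVKLHREYGPITKQGIYHADRTK
PNVPKKRQFQCPNIPAAWAYWETHHMKSSIFEVMIHQNRSYMKMIGLTGQNQLDKKETCCQPAHAYVCNNPHGYK
>STS_synthetic_2
CPKIDSNHCYHFIPYCPAVQYLDITWTMCGDMTLNKSDCHLLFWATALWVENKVQWLSFKCTQWISSMLHRSYNPLHMLG
RFSVEHVHWCTKTQKRMIIQWNMANENLSRSIEKELILTCSAICYGLEKKCAKKPSWMEFFVDWTNGYKRADCDINNFNS
QCSGTQHKGWLHSGQYPQQCEYHSWKLLCYWEVGWQLLRWLYAQPEMYKYIWHVIGPCVWKTCHCMCIMTFCTVSVNNAY
DMSVYSSRYHIIMPVETCKVWDCAHGKNWRYFLIKFVHDWGGDSMIGVATSVSTDLDYSKLHREYLACTCQGIYHADRTK
PNVPKKRQFQCNNIPWAWADWPTHLMKSEIWEVMIHQGRSYMKMIGLRGQNQLDKKETCCQGAHAYLCNNPSHYN
>STS_synthetic_3
CPKIDSNHCYHCIPLCINVCYLDITWTMCGAMTLNKKQCHLLTWATALWVENKPQPLLFKCTQWISSMLIRSYNPLHHLG
SFSVEHMHWWTSTQKRMIINWNMANENLDRSIFKELVLTCSAICYGLAPKSDKNPSPMEFFVDWTSGYKRADNDINNFNS
QCSHAQHKGWLHSIQYPQQCEYWSWGLKCCWEVFWQLCRWLYAQPEMYKHIWHVIGPCVWKTNNVPCIMTFCTVMVNNWY
DVSEYSSRYPEISPGETCKVWVCAHGKQFRYGLIKFVHDWGWISMITVATKRSTDLDYSKLHREYGTCTKQGIYHADRTK
PNVPKKRQFQCNNIPAAWAYYETHHNKSSIFEVMIHQGRSYMWMIGLRGQNQLDKKENCCQVAHAYVCNNPSHYK
>STS_synthetic_4
CPKIDIAPCYHHGPYCPNGCYLDITWTMTGWMTLNLKLAHLLTWATALWVENKIQWLSFKCTQWITSMLHRSYNPLHMLG
WFSVEHMHWCTSTQKRMIYNWNMNNENLSRSIFKELILTCRAICYGIASKSDKKMSPMEKFVDWTDGYKRADDDINNFNS
QCSGAQHKGYLHSIQYPQQWEYWSWKLKCNWEAAWQLCWWLWATPEMYKYIWHVIGPVVWKTCNCMCIMTFCTVFVNNWY
DMSEYSSRYHGISPMETCKVWVCAHGKLHRYFLKKFVHDWGGISMITVATKFSTTLNYSKLHREYGPCTKQGIYHADRTK
PMVPKKRQFQCQTIPFAWAYWETHHMKSSIFEVMIHQGRSYMKMIGLRGQNQLEKKEDCCQVAHAYPCNNPSHYK
>STS_synthetic_5
CPKEDGNHCIHFCPYCPNVCSCDITWTMCGGMTLNKKQCHLLTQATALWVENKVRWFSFKCTQWISNMLHRSYNPLHMQG
RESVEHRCWCTSTQKRMIINWNMANERLSASIVKELIFTCSAICYGLEPKSDAKPSPMEFFVDWTDGYKRADNDINNFNS
QCSGAQHKGWLFSIAYPQQCEAFVWKLKCYWEVGWQLCRWLYAEPEMYKYIWHVICPCSWKTCNCACIMTFKTVSVNNWY
DMSERSCRYHDISQGETCPVWVGKHGKLFRYKLIKFVHQWGGISMTTVATKFMTDLDNMKLHREYGPCTIQGIYHADRTL
PNVPKKRQFQCNNIPCAWAYWETHHMKSSIFEVMIHQGRSYMKMIGLRGQNQLLKKETCCQVAHAYVCNNPSHYK
>STS_synthetic_6
CPKIDSNHCSHFKACEENVCYLDITWTMCGRMFLNKSQCHLLTWATALWVENKVQWQSFCCTQWISSTLHRSYNFLHMLG
RFSVEHMAWCTETQKRMITNWIMANRNLSRRIFKELILTCIAICYGLAPVSCEKPSPMEFFVDWTDGYKRHRNDINNFNS
ECLGAQHKRWLHAIQYLQQCEYWRWKLKCYWEVTWQLCRWLYAQPEMYIYIWWHIGPCEWKTCNMMCIMTFCTVSVNNWC
QMSCYSSRYEGISPGEQCKVWVCAHGKLFRYFLIKFVHVWGGITMITVATKFSTDLDYSVGHREYGMCTKQGIYSADRTK
PNVPKKRQFQCNNIPAAWAYHETHHMQSSIFEVMIHQGRSYMKMIGLRGVNQLDKKETCCQVAHAYVYANPSGYK
>STS_synthetic_7
CPKIDSMHCYHFIPYCPNVCYYDITWTMCVWGELNKKQCHLLTWMTALWVENKPQWVSFKCTQWISSMLHRSYNPLHMLG
RFSVEHMHWCTSTQKRMIINWNMANENLSRSIFKELIFTCSAICYGLGPKSDKKPSPMEFFVDWTEGLKRADNDINNFNP
QRSGAQHKGWLHSIQVPIQCEYWSWKFKSYWEIGWQLSVWLYAQPKMYKYIWHVIGPCVHKTCNCMCGMTFCTVSVNNWY
DMSEYSRRCHGISPGERCKVWVCAQGKLFRYFLIGFVHDMGEISMITYATKFTTDLDYSKLHREYGPCTKQGIYFADRTN
PNVPKKRQTLCNFIDAAWAYWETHHMKSSEFEVMIHQPRSYYKMDGLEGQNQKDKKETCAQVAHAYVCGNPSHYK
>STS_synthetic_8
WKKIDSNHCIHFIPMCPNVCYLDVTWTMCGPMTLNKKQCHLLTWATALQVENKVQWLSFKKRQWPSSMLHRHYNPLHMLG
RFSVEHMHWCTSTQYRMSINWNMAVENLSRSIFKELIKFCSFICYGLAPKSIKKPSPDHHFVDQTDGYKRADNDINNFNS
QCSGAQHKGWLHGVQYPQQCEYWSWKLKCYEEVGWQLCRWLYCQEEMYKYIWQVIGPCVRKTCNCMCIMTFCTVSVNNWY
DMSEYSSRYHGISPGETFKVWVCYHGKQFRYFLIYFVHDWGGISMITVATKFSTDLDYSKLHRFYGPCTKFGQVKIDRTK
PNVPKKRQFFCNNIPANWAYMETHHMKSSIFEVMIHQGRSYMKMIGYRGQNQLDKKFTCCQVAHADVCNNPSHYK
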