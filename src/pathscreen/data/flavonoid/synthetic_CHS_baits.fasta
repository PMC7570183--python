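>CHS_synthetic_1
CIKIVSNWEYGFIPYMPNVYYLDCTPTMCGKMNLNKKQCHLKTTQTHCDVENKVQALSPNCEQVEVSSLHRQYNPLHMLP
RFAVEYMHWTNSTQKPMTIDHNMANRDLSRSINKELKLTGNAICYGLAYKSDSKPPHMEPKVDPRDYDMAFDNDSNNFRS
NCSMAQQKVWYHSIQYPQQCEYWSWKLKCYMRMGWQLPRWLYTQPHMYKWETHVTGKSIMKNCNCMCIYTFTTKSVTTWY
DMSMCHSRYRFIWPSEWYKVWVCAHGKLFDIFMIKEVHDWGGRHAKTVVTKFMTGADYSKLHLEYGPATELGIFHADRTK
PEVPKKRQFGCVNIPAGSATWETHIMVPSIVEVMIHQGRSRMKMAGLRGQNQLCVKETPCQVAHAYVPNNWSPYK
>CHS_synthetic_2
CMKKVSNWEYHFNPSMPNVYYLDITWTMCGGMTLNKKQCHLKLTQTHCDVENKDQHLSPKCTQWESSSLHRSYNGLHMLP
RFAVEYMHWTNSTCKRGIIDHNMANNDLSRSIFKELYLTGFACCYGLAPKSDKKPPHIEPFVPPTDYYMRFANDINNFYS
LCSGAQQKVWYHSIMYPQSCEYLDWKLKCYMFMGWQLCRWLYTQPWMYKWEKHKTGPSIWKNCNCNCIMTFTLKSVMRKY
FMSECSSRWRFINPSAWYKFWVCAHGKLFDYDMIKEVHDWGWFHEKTVVTGFSTGADYSVLHLEYGPATEQGIFHADRTK
PEVPKKRQFQCNNIPAGSATWYTHIMKSSIVEVMIHQGMSYMKMIGLRGQNQLDKKETSCTVAHAYVVNNWSHYK
>CHS_synthetic_3
WIKICSNWEYHFIPYTPNVYYLVITWTGCGWMTINKKQCHLKTSITHCDVENKVQHLSPKCTQWHQESLHDPYNPLKMPP
RFAVEYMHWTNSTQKRMMIDFNMANRDLSRSIFKELILTYSAICYGTAPKCDKKPPHMEPDTDPTDYYMRCDNDINNFRS
QCSGAQQKVWYTSIQYPQQEEYWSWKLKCYCFMGWQSCCWLYTLPWMNKWEVHVRGPSIWKNCNCMNISTFTTKSVSEWY
DMSECSSRYRFIWPSMWYKVWVCAHGKFFDYFMIKEVHDWGGRHAKTVVTKFSTGADYSKLHLEYGPATEQGIFHADRTK
PEVPKKRQFQCQNIPAGSATWETHIMKSSIVPVMIHQMRSYMKMCGLRGINWLDKKETSCQVAHAYVVENWSHYK
>CHS_synthetic_4
CIKIVSNWEYHFIPYMPNVYELDITWTMCGWMTLNKKDCHLKTTQTHCDVENKVQHLSPKCTQWESSSLHRMYNPLEMLP
RFAVEYMHWTNSTIKRMIIDHNMANRDLSRSIFKELILTGSAICIGLAPKSDKKPPHMEPWKDPTDYYMRFDNDINEFRS
QCSGAQQKVWYHSIQYPQQCEYWSKKLKCWMFMGWQLNRWLYTQPWMKKWETHVTGPSTCKNIRCMCIMTFTTKTVTRWY
DMSECSSRYRFIWPSEWYKVWVCAHGALFDYFMIKEVHDWGGRHAKTVVTKFSTGADYSKLKLEYGPATEQGIFHADRTK
PEVPKKRQFQCNNIWKHSRTWETHIMKSSIVEVMIHQGRSYMKMIGQRGPNQLDKKETSRQVQHAYVVNNWSHYK
>CHS_synthetic_5
CIKIVLNSEYHFIPYMPNVYYLDIRWTMCGWMTLNKKQCHLHTTQTHCDVEPMVSHLSPKCTQWESSSLHRSYLPLHMRP
MFHVEYRHWINSTQKRMKIDHNMANRDLSRSIFKELISTGYAICYGHAPKSDKKPPHMEPFVDPTDYYMRFDGDINNMRS
QCSGAQQKVWYHSIQYPQQCEYWSWKLKCYMFMGWHLCRWLYTQPWMYKWETHPDGPSKPKNCNCMCICVFTTKSVFRWY
DMWWCSSRYRFIWGSEWYKVWVCAHGDLFDFFMIKEVHIWGGRHAKTVVINFDTGADYSELHTSYGIATEQGIFHADRTK
PEVPKKRQFQCNNIPAGIATWETHISNSSVVEVMIHQGRSYMKKIGLRGQEQLTKKETSCQGAHAYVVNNWSHYK
>CHS_synthetic_6
CIKIVSNEEYHFIPYMPNVYLLDITWTMCGWMTLNKCQCRLKTTQTHCDVKNKVQHLSPKCTQWESFSLHRSYNPLHMLP
RFAVEYMHWTNSTQKVRLIDHNIANRDLSRSIQMELILTGFAICYGLAPFNDKKPPHMEPFVDPTGYYMRFDNDINNKRS
QCIGAQQYVWYHSIQEPQQCEYWSWKLSCYMFPGWQLCRWLYWQPWMYKWETHVTGPSIWKNCNCSCYMTFTWKSVTSWY
DMSECSSRYRFIWPSEWYKVWVCAHGKLFDYWMTKEVHDWGGRHAKCVVTKFSTFADYSKLHLEYGPFTEQGIFHADRTK
PEVPKKRQFQCNNIPAGSATSETGIMKSRIVEVMWMQGRSYMKAIGHRGQWYLDKKETSCQVAHAYVVNNFSHYK
>CHS_synthetic_7
CIKIVSNWEGHFIPSMPNVYYLDITWTMCGWKTLNKKQCHLKTTQVACDVENKNQHLSNKCTQWESSSLHRSYNPLHMLP
RFAVEYMHWTNSTQKRMIIHHFMAERDLSRSIFKRLILTGSAICYGLASISDKKPPHMEPFVDPTDYYMRFDTDICNFRG
QCSVAQQKVWYHSIQYPQQCEYWSNKLKCYMFMGWQLERWLYTQPWMYKWETHVTGPSIWKNCNCMCQMTMTVKSVTRWY
DMSECSSQYRFIWPCEWYKVWVCAHGKGFDYFMIHEVHDIGGRHAKTVVHKFDTGADLSKLHLEYGPFTEQGIFHADRTK
PEVPKKRQFQCNNIPAGAPTWETHIMKSSIVEVMIHQGRSYDKMIGLRGQNQLDKKETGCQCAHAYVYNNWHDYK
>CHS_synthetic_8
CYKIVSNWEYHFIPYMPNRYYLDITWTMCQWMTLNKKQCHLKTTQTHCDVYHKVQHLSPKCTQWVHSSLLRSYNPLHMLP
RFAVEYMHHKNSTQKRCIIDHNMANRDLSRSIFKELALTGSAICYGLAPKSDKKPPHMEPFANPTNYYMRFINPNNNFRS
QCSGAQQKPWYHSIQYPQQCEYWSWKLKCYPFMGWIACRWLYCQAWMYKWEYHVTEPSIWKNCNCMCIMTFTTNSVTLWY
HMSECSSRYRFIWPSEWYKVWVCEHPKLFYWFMIRSVMDLGAFHAKPVVTKFSTLADPSKLHLEYGPPTEQGIFHADRTK
PEVPKKRQFKCNCIPAGDATWEFHIMKSSIVEVMIHQGRSCMKMIGLRGQNQLDKKERSCQDAHAYVVNNWSHYE
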